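"""Alignment, p-distance, NJ exactness, bootstrap, family partitioning."""

import numpy as np
import pytest

from nbslrr.phylogeny import (
    DistanceMatrix,
    bootstrap_support,
    build_msa,
    comparative_mode,
    nj_tree,
    partition_families,
    pdistance_matrix,
)
from nbslrr.synthetic import generate_family_set, mutate_protein, random_protein


def tree_path_distances(tree):
    """Leaf-to-leaf path-length metric induced by a tree (oracle helper)."""
    dists = {}

    def walk(node):
        if node.is_leaf:
            return {node.label: 0.0}
        maps = []
        for child in node.children:
            sub = walk(child)
            maps.append({leaf: d + child.length for leaf, d in sub.items()})
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for la, da in maps[i].items():
                    for lb, db in maps[j].items():
                        dists[frozenset((la, lb))] = da + db
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    walk(tree.root)
    return dists


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary topology with positive branch lengths; returns
    the exact pairwise path-distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    # build by sequential taxon insertion on a growing edge list
    import itertools

    edges = {}  # (a, b) -> length, over pseudo-nodes
    next_internal = [n_taxa]

    def new_len():
        return float(rng.uniform(0.1, 2.0))

    # start from a 3-star
    center = next_internal[0]
    next_internal[0] += 1
    adj = {center: []}
    lengths = {}
    for i in range(3):
        adj.setdefault(i, []).append(center)
        adj[center].append(i)
        lengths[frozenset((i, center))] = new_len()
    for i in range(3, n_taxa):
        # pick a random edge and subdivide it
        all_edges = list(lengths)
        edge = all_edges[int(rng.integers(len(all_edges)))]
        a, b = tuple(edge)
        mid = next_internal[0]
        next_internal[0] += 1
        L = lengths.pop(edge)
        adj[a].remove(b)
        adj[b].remove(a)
        split = float(rng.uniform(0.2, 0.8))
        adj.setdefault(mid, [])
        for u, w in ((a, L * split), (b, L * (1 - split))):
            adj[u].append(mid)
            adj[mid].append(u)
            lengths[frozenset((u, mid))] = w
        adj[i] = [mid]
        adj[mid].append(i)
        lengths[frozenset((i, mid))] = new_len()
    # BFS distances between leaves
    import collections

    for s in range(n_taxa):
        dist = {s: 0.0}
        queue = collections.deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + lengths[frozenset((u, v))]
                    queue.append(v)
        for t in range(n_taxa):
            D[s, t] = dist[t]
    D = (D + D.T) / 2  # remove float asymmetry from per-source traversals
    np.fill_diagonal(D, 0.0)
    return labels, D


class TestMSA:
    def test_identical_sequences_align_gap_free(self):
        aln = build_msa({"a": "MKVLAG", "b": "MKVLAG", "c": "MKVLAG"})
        assert all(seq == "MKVLAG" for _, seq in aln)

    def test_single_deletion_gives_one_gap_column(self):
        aln = dict(build_msa({"a": "ACDEF", "b": "ACEF"}))
        assert len(aln["a"]) == 5
        assert aln["a"] == "ACDEF"
        assert aln["b"].count("-") == 1

    def test_alignment_length_at_least_longest_input(self):
        seqs = {"a": "MKVLAGRR", "b": "MKV", "c": "MKVLAGRRDD"}
        aln = build_msa(seqs)
        assert len(aln[0][1]) >= 10

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_msa({"a": "MKV"})


class TestPDistance:
    def test_identical_pair_is_zero(self):
        dm = pdistance_matrix([("a", "AAAA"), ("b", "AAAA")])
        assert dm.values[0, 1] == 0.0

    def test_quarter_distance(self):
        dm = pdistance_matrix([("a", "AAAA"), ("b", "AAAT")])
        assert dm.values[0, 1] == 0.25

    def test_pairwise_deletion_ignores_gapped_sites(self):
        dm = pdistance_matrix([("a", "A-CD"), ("b", "AAC-")])
        assert dm.values[0, 1] == 0.0  # 2 comparable sites, both equal

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError):
            pdistance_matrix([("a", "A--"), ("b", "-AA")])

    def test_matrix_invariants(self):
        rng = np.random.default_rng(1)
        seqs = [(f"s{i}", "".join(rng.choice(list("ACDEFGH"), 30)))
                for i in range(6)]
        dm = pdistance_matrix(seqs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert dm.values.min() >= 0 and dm.values.max() <= 1


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # distances from the unrooted tree ((A:1,B:2):1,(C:3,D:1))
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels, D))
        sides = set(tree.bipartitions())
        assert sides == {frozenset({"C", "D"})}
        paths = tree_path_distances(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert paths[frozenset((a, b))] == pytest.approx(D[i, j])

    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        D = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(labels, D))
        by_label = {c.label: c.length for c in tree.root.children}
        assert by_label["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert by_label["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert by_label["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_two_taxa_trivial_tree(self):
        tree = nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]])))
        assert sorted(c.label for c in tree.root.children) == ["a", "b"]
        assert sum(c.length for c in tree.root.children) == pytest.approx(0.5)

    def test_random_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(4, 9))
            labels, D = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(labels, D))
            paths = tree_path_distances(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    assert abs(
                        paths[frozenset((labels[i], labels[j]))] - D[i, j]
                    ) < 1e-9

    def test_matches_independent_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        for trial in range(10):
            n = int(rng.integers(5, 9))
            labels, D = random_additive_tree(n, rng)
            ours = set(nj_tree(DistanceMatrix(labels, D)).bipartitions())
            ref_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
            full = frozenset(labels)
            ref_canon = min(labels)
            theirs = set()
            for node in ref_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n:
                    theirs.add(full - side if ref_canon in side else side)
            assert ours == theirs

    def test_blocky_matrix_splits_the_blocks(self):
        labels = [f"x{i}" for i in range(6)]
        D = np.full((6, 6), 0.8)
        D[:3, :3] = 0.1
        D[3:, 3:] = 0.1
        np.fill_diagonal(D, 0)
        tree = nj_tree(DistanceMatrix(labels, D))
        sides = {frozenset(s) for s in tree.bipartitions()}
        assert frozenset(labels[3:]) in sides or frozenset(labels[:3]) in sides

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [0.5, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))


@pytest.fixture(scope="module")
def family_alignment():
    seqs, labels = generate_family_set(6, 6, 0.05, 0.4, seed=5)
    return build_msa(seqs), labels


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self, family_alignment):
        aln, _ = family_alignment
        tree = bootstrap_support(aln, n_replicates=1, seed=0)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_supports_bounded_and_only_fulltree_bipartitions_scored(
        self, family_alignment
    ):
        aln, _ = family_alignment
        tree = bootstrap_support(aln, n_replicates=50, seed=0)
        assert set(tree.supports) == set(tree.bipartitions())
        assert all(0 <= s <= 100 for s in tree.supports.values())

    def test_supports_invariant_to_leaf_input_order(self, family_alignment):
        aln, _ = family_alignment
        fwd = bootstrap_support(aln, n_replicates=30, seed=2)
        rev = bootstrap_support(aln[::-1], n_replicates=30, seed=2)
        assert fwd.supports == rev.supports

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support([("a", "AA"), ("b", "AA"), ("c", "AA")])


class TestFamilyPartition:
    def test_planted_families_fully_recovered(self):
        seqs, labels = generate_family_set(8, 8, 0.05, 0.4, seed=7)
        tree = bootstrap_support(build_msa(seqs), n_replicates=100, seed=1)
        part = partition_families(tree, {"TIR_01": "TIR", "CC_01": "CC"})
        assert part.resolved
        assert part.boundary_support >= 90
        assert all(part.family[leaf] == fam for leaf, fam in labels.items())
        # subfamilies nest inside families
        for leaf, sub in part.subfamily.items():
            assert sub.startswith(part.family[leaf])

    def test_single_family_has_no_boundary(self):
        seqs, labels = generate_family_set(5, 0, 0.1, None, seed=3)
        tree = bootstrap_support(build_msa(seqs), n_replicates=20, seed=1)
        part = partition_families(tree, {"TIR_01": "TIR"})
        assert part.resolved
        assert part.boundary_support is None
        assert set(part.family.values()) == {"TIR"}

    def test_conflicting_anchors_reported_unresolved(self):
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 0.1, 0.8, 0.8], [0.1, 0, 0.8, 0.8],
             [0.8, 0.8, 0, 0.1], [0.8, 0.8, 0.1, 0]]
        )
        tree = nj_tree(DistanceMatrix(labels, D))
        part = partition_families(
            tree, {"A": "TIR", "C": "TIR", "B": "CC", "D": "CC"}
        )
        assert not part.resolved
        assert "separate" in part.diagnostics

    def test_singleton_subfamilies_allowed(self):
        seqs, labels = generate_family_set(8, 8, 0.05, 0.4, seed=7)
        # one extra leaf far from everything becomes a singleton subfamily
        rng = np.random.default_rng(0)
        seqs["TIR_odd"] = mutate_protein(seqs["TIR_01"], 0.45, rng)
        tree = bootstrap_support(build_msa(seqs), n_replicates=50, seed=1)
        part = partition_families(tree, {"TIR_01": "TIR", "CC_01": "CC"})
        counts = {}
        for sub in part.subfamily.values():
            counts[sub] = counts.get(sub, 0) + 1
        assert 1 in counts.values()


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(9)
    root = random_protein(180, rng)
    panel_seqs, panel_fam, panel_sub = {}, {}, {}
    ancestors = {}
    for k in range(4):
        ancestors[k] = mutate_protein(root, 0.25, rng)
        for m in range(3):
            name = f"ref{k}_{m}"
            panel_seqs[name] = mutate_protein(ancestors[k], 0.04, rng)
            panel_fam[name] = "CC"
            panel_sub[name] = f"N{k + 1}"
    return panel_seqs, panel_fam, panel_sub, ancestors, rng


class TestComparativeMode:
    def test_query_identical_to_reference_gets_its_subfamily(self, panel):
        panel_seqs, panel_fam, panel_sub, _, _ = panel
        queries = {"q1": panel_seqs["ref2_0"]}
        table, _ = comparative_mode(
            queries, {"q1": "CC"}, panel_seqs, panel_fam, panel_sub,
            n_replicates=50, seed=0,
        )
        assert table.loc[0, "assigned_subfamily"] == "N3"

    def test_query_from_planted_clade_ancestor_assigned_to_it(self, panel):
        panel_seqs, panel_fam, panel_sub, ancestors, rng = panel
        queries = {"q1": mutate_protein(ancestors[1], 0.04, rng)}
        table, _ = comparative_mode(
            queries, {"q1": "CC"}, panel_seqs, panel_fam, panel_sub,
            n_replicates=50, seed=0,
        )
        assert table.loc[0, "assigned_subfamily"] == "N2"

    def test_family_without_references_is_lineage_specific(self, panel):
        panel_seqs, panel_fam, panel_sub, _, _ = panel
        queries = {"q1": random_protein(180, np.random.default_rng(2))}
        table, _ = comparative_mode(
            queries, {"q1": "TIR"}, panel_seqs, panel_fam, panel_sub,
            n_replicates=10, seed=0,
        )
        assert table.loc[0, "assigned_subfamily"] == "lineage-specific"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            comparative_mode({"q": "MKV"}, {"q": "CC"}, {}, {}, {})
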