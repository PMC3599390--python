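"""Neighbor-joining phylogeny of P-loop..GLPL cores with bootstrap support.

Implements the classical pipeline used for this gene family: multiple
alignment of the conserved NBS cores, p-distances with pairwise deletion of
gaps, neighbor joining (Saitou-Nei branch lengths, deterministic
lexicographic tie-breaking), non-parametric bootstrap over alignment
columns, and partitioning of the resulting tree into the TIR and CC
families plus supported subfamilies. Trees are unrooted; supports are
percentages in [0, 100] scored only for the bipartitions of the full-data
tree.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GAP = ord("-")


# ---------------------------------------------------------------------------
# alignment


def _as_items(seqs) -> list:
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len({k for k, _ in items}) != len(items):
        raise ValueError("duplicate sequence labels")
    return items


def build_msa(cores, mafft_exe: str = "mafft") -> list:
    """Align protein sequences with MAFFT (deterministic for fixed input).

    ``cores`` is a label -> sequence mapping (or list of pairs); returns a
    list of ``(label, aligned_sequence)`` in the input order.
    """
    items = _as_items(cores)
    if len(items) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    if shutil.which(mafft_exe) is None:
        raise RuntimeError(f"{mafft_exe} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fa"
        fasta.write_text(
            "".join(f">s{i}\n{seq}\n" for i, (_, seq) in enumerate(items))
        )
        res = subprocess.run(
            [mafft_exe, "--auto", "--amino", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True,
        )
    aligned: dict[int, list] = {}
    idx = -1
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            idx = int(line[2:])
            aligned[idx] = []
        elif line.strip():
            aligned[idx].append(line.strip())
    out = [(label, "".join(aligned[i]).upper()) for i, (label, _) in enumerate(items)]
    lengths = {len(s) for _, s in out}
    if len(lengths) != 1:
        raise RuntimeError("mafft returned ragged alignment")
    return out


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal.

    p-distances are bounded by 1; general additive distances (e.g. summed
    branch lengths) are not, so the upper bound is only enforced when
    ``bounded`` is set (as :func:`pdistance_matrix` does).
    """

    labels: list
    values: np.ndarray
    bounded: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if self.bounded and np.any(self.values > 1 + 1e-12):
            raise ValueError("p-distances must lie in [0, 1]")


def _encode_alignment(alignment) -> tuple[list, np.ndarray, np.ndarray]:
    items = _as_items(alignment)
    L = len(items[0][1])
    if any(len(s) != L for _, s in items):
        raise ValueError("aligned sequences must have equal length")
    arr = np.frombuffer(
        "".join(s.upper() for _, s in items).encode("ascii"), dtype=np.uint8
    ).reshape(len(items), L)
    gaps = arr == GAP
    return [k for k, _ in items], arr, gaps


def _pdist(arr: np.ndarray, gaps: np.ndarray, on_empty: str = "raise") -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gaps[i] & ~gaps[j]
            nc = int(both.sum())
            if nc == 0:
                if on_empty == "raise":
                    raise ValueError(
                        f"sequences {i} and {j} share no comparable sites"
                    )
                d[i, j] = d[j, i] = 1.0
                continue
            mm = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mm / nc
    return d


def pdistance_matrix(alignment) -> DistanceMatrix:
    """p-distance with pairwise deletion: for each pair, the mismatch
    fraction over sites where both sequences are ungapped."""
    labels, arr, gaps = _encode_alignment(alignment)
    return DistanceMatrix(labels, _pdist(arr, gaps), bounded=True)


# ---------------------------------------------------------------------------
# trees


class Node:
    __slots__ = ("label", "length", "children", "support", "key")

    def __init__(self, label=None, length=0.0, children=None):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = children or []
        self.support: float | None = None
        # deterministic sort key: smallest leaf label in the subtree
        self.key = label if label is not None else min(c.key for c in self.children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset:
        if self.is_leaf:
            return frozenset((self.label,))
        out = frozenset()
        for c in self.children:
            out |= c.leaf_labels()
        return out

    def _newick(self, with_supports: bool, hide_leq) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.length:.6g}"
        inner = ",".join(
            c._newick(with_supports, hide_leq)
            for c in sorted(self.children, key=lambda c: c.key)
        )
        label = ""
        if with_supports and self.support is not None:
            if hide_leq is None or self.support > hide_leq:
                label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class PhyloTree:
    root: Node
    labels: list = field(default_factory=list)
    supports: dict = field(default_factory=dict)  # canonical side -> percent

    def __post_init__(self):
        if not self.labels:
            self.labels = sorted(self.root.leaf_labels())

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.labels)

    def canonical(self, side: frozenset) -> frozenset:
        """Canonical representation of a bipartition: the side not containing
        the lexicographically smallest leaf."""
        ref = min(self.labels)
        return self.leaf_set - side if ref in side else frozenset(side)

    def bipartitions(self) -> dict:
        """Canonical side -> defining internal node, for every internal edge."""
        out: dict[frozenset, Node] = {}

        def walk(node: Node, at_root: bool):
            for child in node.children:
                if not child.is_leaf:
                    out[self.canonical(child.leaf_labels())] = child
                walk(child, False)

        walk(self.root, True)
        return out

    def to_newick(self, with_supports: bool = True, hide_leq=None) -> str:
        inner = ",".join(
            c._newick(with_supports, hide_leq)
            for c in sorted(self.root.children, key=lambda c: c.key)
        )
        return f"({inner});"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    Q-matrix ties are broken by the lexicographically smallest pair of
    subtree keys; negative branch lengths are clamped to zero with the
    deficit transferred to the sibling branch. Additive matrices are
    recovered exactly.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    if n == 2:
        d = float(dm.values[0, 1])
        children = [Node(lbl, d / 2) for lbl in dm.labels]
        return PhyloTree(Node(children=children))

    nodes = [Node(lbl) for lbl in dm.labels]
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> Node:
        a, b = nodes[i], nodes[j]
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        a.length, b.length = max(li, 0.0), max(lj, 0.0)
        return Node(children=[a, b])

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((nodes[active[a]].key, nodes[active[b]].key))), a, b)
            for a, b in cand
            if a < b
        )
        ai, bi = best[1], best[2]
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = dij / 2 + (r[ai] - r[bi]) / (2 * (m - 2))
        parent = join(i, j, li, dij - li)
        # distances from the new node to the remaining taxa
        new = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new[k] = max((D[i, k] + D[j, k] - dij) / 2, 0.0)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new[:-1]
        D[:-1, -1] = new[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = max(float(lk), 0.0)
    return PhyloTree(Node(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_support(
    alignment, n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicates whose NJ tree contains each bipartition of the
    full-data tree. The replicate column draws depend only on ``seed`` and
    the replicate index, so supports are invariant to leaf input order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    items = _as_items(alignment)
    if len(items) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    labels, arr, gaps = _encode_alignment(items)
    tree = nj_tree(DistanceMatrix(labels, _pdist(arr, gaps)))
    target = tree.bipartitions()
    counts = {side: 0 for side in target}
    L = arr.shape[1]
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, L, size=L)
        d = _pdist(arr[:, cols], gaps[:, cols], on_empty="max")
        rep_tree = nj_tree(DistanceMatrix(labels, d))
        rep_sides = set(rep_tree.bipartitions())
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    for side, node in target.items():
        node.support = supports[side]
    tree.supports = supports
    return tree


# ---------------------------------------------------------------------------
# family partition


@dataclass
class FamilyPartition:
    family: dict
    subfamily: dict
    boundary_support: float | None
    resolved: bool
    diagnostics: str = ""


def partition_families(
    tree: PhyloTree,
    anchors: dict,
    min_support: float = 50.0,
    min_subfamily_size: int = 2,
) -> FamilyPartition:
    """Split a tree into TIR and CC families using anchor leaves.

    The family boundary is the maximal-support bipartition placing all TIR
    anchors on one side and all CC anchors on the other (single-leaf sides
    count as trivially supported edges). Subfamilies are the maximal clades
    within a family with support above ``min_support`` and at least
    ``min_subfamily_size`` leaves; uncovered leaves become singleton
    subfamilies.
    """
    leaves = tree.leaf_set
    tir = frozenset(k for k, v in anchors.items() if v == "TIR")
    cc = frozenset(k for k, v in anchors.items() if v == "CC")
    if not (tir | cc) <= leaves:
        raise ValueError("anchors must be tree leaves")
    if not tir or not cc:
        fam = "TIR" if tir else "CC"
        family = {leaf: fam for leaf in leaves}
        sub = _subfamilies(tree, leaves, fam, min_support, min_subfamily_size)
        return FamilyPartition(family, sub, None, True, "single family, no boundary")

    candidates: list[tuple[float, frozenset]] = []
    sides = {side: node.support for side, node in tree.bipartitions().items()}
    for leaf in leaves:  # leaf edges are trivially present bipartitions
        sides.setdefault(frozenset((leaf,)), 100.0)
    for side, support in sides.items():
        comp = leaves - side
        if (tir <= side and cc <= comp) or (cc <= side and tir <= comp):
            candidates.append((support if support is not None else 0.0, side))
    if not candidates:
        return FamilyPartition(
            {}, {}, None, False,
            "no bipartition cleanly separates the TIR and CC anchors",
        )
    # at equal support prefer the deepest (most balanced) split: a leaf edge
    # trivially separates the anchors but is not the family boundary
    n_leaves = len(leaves)
    candidates.sort(
        key=lambda t: (-t[0], -min(len(t[1]), n_leaves - len(t[1])), sorted(t[1]))
    )
    support, side = candidates[0]
    tir_side = side if tir <= side else leaves - side
    family = {leaf: ("TIR" if leaf in tir_side else "CC") for leaf in leaves}
    sub: dict[str, str] = {}
    sub.update(_subfamilies(tree, tir_side, "TIR", min_support, min_subfamily_size))
    sub.update(
        _subfamilies(tree, leaves - tir_side, "CC", min_support, min_subfamily_size)
    )
    return FamilyPartition(family, sub, support, True)


def _subfamilies(
    tree: PhyloTree,
    family_leaves: frozenset,
    family: str,
    min_support: float,
    min_size: int,
) -> dict:
    supported = [
        side
        for side, node in tree.bipartitions().items()
        if side <= family_leaves
        and len(side) >= min_size
        and (node.support is None or node.support > min_support)
    ]
    supported.sort(key=len, reverse=True)
    chosen: list[frozenset] = []
    for side in supported:
        if not any(side <= c for c in chosen):
            chosen.append(side)
    chosen.sort(key=lambda s: (-len(s), sorted(s)))
    out: dict[str, str] = {}
    for i, clade in enumerate(chosen, 1):
        for leaf in clade:
            out[leaf] = f"{family}{i}"
    k = len(chosen)
    for leaf in sorted(family_leaves - set(out)):
        k += 1
        out[leaf] = f"{family}{k}"
    return out


# ---------------------------------------------------------------------------
# comparative mode


def comparative_mode(
    query_cores: dict,
    query_families: dict,
    panel_cores: dict,
    panel_families: dict,
    panel_subfamilies: dict,
    n_replicates: int = 200,
    seed: int = 0,
    min_support: float = 50.0,
) -> tuple[pd.DataFrame, dict]:
    """Place query NBS cores relative to a labelled reference panel.

    Families are analysed separately. Each query is assigned the majority
    reference subfamily of its smallest supported enclosing clade that
    contains reference leaves, or ``lineage-specific`` when no supported
    clade joins it to any reference (including when its family has no
    reference representatives at all).
    """
    if not panel_cores:
        raise ValueError("empty reference panel")
    rows: list[dict] = []
    trees: dict[str, PhyloTree] = {}
    for fam in sorted(set(query_families.values())):
        queries = {q: s for q, s in query_cores.items() if query_families[q] == fam}
        refs = {r: s for r, s in panel_cores.items() if panel_families[r] == fam}
        if not refs:
            for q in sorted(queries):
                rows.append(_assign_row(q, fam, "lineage-specific", None, 0))
            continue
        combined = {**refs, **queries}
        aln = build_msa(combined)
        if len(combined) >= 4:
            tree = bootstrap_support(aln, n_replicates=n_replicates, seed=seed)
            trees[fam] = tree
            sides = {
                side: node.support for side, node in tree.bipartitions().items()
            }
            full = tree.leaf_set
            for q in sorted(queries):
                cands = []
                for side, sup in sides.items():
                    if sup is None or sup <= min_support:
                        continue
                    q_side = side if q in side else full - side
                    if len(q_side) < len(full):
                        cands.append((len(q_side), sorted(q_side), q_side, sup))
                if not cands:
                    rows.append(_assign_row(q, fam, "lineage-specific", None, 0))
                    continue
                cands.sort(key=lambda t: (t[0], t[1]))
                _, _, side, sup = cands[0]
                subfams = sorted(panel_subfamilies[r] for r in side if r in refs)
                if not subfams:
                    rows.append(_assign_row(q, fam, "lineage-specific", sup, len(side)))
                    continue
                counts = pd.Series(subfams).value_counts()
                top = counts.max()
                call = sorted(counts[counts == top].index)[0]
                rows.append(_assign_row(q, fam, call, sup, len(side)))
        else:
            # too few taxa for a supported tree: nearest reference by p-distance
            dm = pdistance_matrix(aln)
            for q in sorted(queries):
                qi = dm.labels.index(q)
                dists = [
                    (dm.values[qi, dm.labels.index(r)], r) for r in sorted(refs)
                ]
                dists.sort()
                rows.append(
                    _assign_row(q, fam, panel_subfamilies[dists[0][1]], None, 2)
                )
    return pd.DataFrame(rows), trees


def _assign_row(query, family, subfamily, support, clade_size) -> dict:
    return {
        "query": query,
        "family": family,
        "assigned_subfamily": subfamily,
        "clade_support": support,
        "clade_size": clade_size,
    }
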