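"""Genome-structure analyses: intron phases, gene clusters, duplications.

The cluster rule: two neighbouring NBS genes belong to one cluster when
they are less than ``max_gap`` apart (default 200 kb, start-to-start) with
at most ``max_intervening`` (default 7, i.e. "fewer than eight") non-NBS
genes between them; maximal chains of length >= 2 are clusters.

Duplicate pairs are called from a protein-identity matrix (best partner per
gene, identity >= threshold); a pair inside one cluster is a tandem
duplication, any other pair is segmental.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .models import GeneModel


def intron_stats(gene: GeneModel) -> tuple[int, list]:
    """Intron count and phases of a gene model.

    The phase of an intron is the cumulative CDS length upstream of it
    modulo 3 (0/1/2 bases into the interrupted codon).
    """
    lengths = gene.coding_exon_lengths
    if not lengths:
        raise ValueError(f"{gene.gene_id}: gene has no exons")
    phases = []
    cum = 0
    for length in lengths[:-1]:
        cum += length
        phases.append(cum % 3)
    return len(lengths) - 1, phases


@dataclass
class GeneCluster:
    cluster_id: str
    chromosome: str
    members: list  # gene ids ordered by position
    span_bases: int

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("clusters need >= 2 members")


def _anchor(gene: GeneModel, anchor: str) -> int:
    if anchor == "start":
        return gene.start
    if anchor == "end":
        return gene.end
    if anchor == "midpoint":
        return (gene.start + gene.end) // 2
    raise ValueError(f"unknown anchor {anchor!r}")


def cluster_rule(
    left: GeneModel,
    right: GeneModel,
    intervening: int,
    max_gap: int = 200_000,
    max_intervening: int = 7,
    anchor: str = "start",
) -> bool:
    """Pairwise chaining rule between two consecutive NBS genes."""
    if left.chromosome != right.chromosome:
        return False
    dist = abs(_anchor(right, anchor) - _anchor(left, anchor))
    return dist < max_gap and intervening <= max_intervening


def detect_clusters(
    nbs_genes: Sequence[GeneModel],
    all_genes: Sequence[GeneModel],
    max_gap: int = 200_000,
    max_intervening: int = 7,
    anchor: str = "start",
) -> list[GeneCluster]:
    """Chain consecutive NBS genes per chromosome into clusters.

    ``all_genes`` supplies the non-NBS gene track used for the intervening
    count (genes whose anchor lies strictly between the two NBS anchors).
    """
    nbs_ids = {g.gene_id for g in nbs_genes}
    non_nbs = [g for g in all_genes if g.gene_id not in nbs_ids]
    by_chrom: dict[str, list] = {}
    for g in sorted(nbs_genes, key=lambda g: (g.chromosome, _anchor(g, anchor), g.gene_id)):
        by_chrom.setdefault(g.chromosome, []).append(g)
    non_by_chrom: dict[str, np.ndarray] = {}
    for chrom in by_chrom:
        pos = sorted(_anchor(g, anchor) for g in non_nbs if g.chromosome == chrom)
        non_by_chrom[chrom] = np.asarray(pos, dtype=np.int64)

    clusters: list[GeneCluster] = []
    n = 0
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        positions = non_by_chrom[chrom]
        chain = [genes[0]]
        for left, right in zip(genes, genes[1:]):
            a, b = _anchor(left, anchor), _anchor(right, anchor)
            intervening = int(
                np.searchsorted(positions, b, side="left")
                - np.searchsorted(positions, a, side="right")
            )
            if cluster_rule(left, right, intervening, max_gap, max_intervening, anchor):
                chain.append(right)
            else:
                if len(chain) >= 2:
                    n += 1
                    clusters.append(_make_cluster(n, chrom, chain))
                chain = [right]
        if len(chain) >= 2:
            n += 1
            clusters.append(_make_cluster(n, chrom, chain))
    return clusters


def _make_cluster(n: int, chrom: str, chain: list) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"cluster{n}",
        chromosome=chrom,
        members=[g.gene_id for g in chain],
        span_bases=chain[-1].end - chain[0].start,
    )


@dataclass
class DuplicationEvent:
    gene_a: str
    gene_b: str
    kind: str  # "tandem" | "segmental"
    identity_fraction: float

    def __post_init__(self):
        if not 0 <= self.identity_fraction <= 1:
            raise ValueError("identity_fraction must be in [0, 1]")


def protein_identity_matrix(proteins: dict) -> tuple[list, np.ndarray]:
    """Pairwise global-alignment identity (1 - edit distance / longer length)
    for a mapping of gene id -> protein sequence."""
    labels = list(proteins)
    n = len(labels)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = proteins[labels[i]], proteins[labels[j]]
            dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            ident = 1.0 - dist / max(len(a), len(b))
            mat[i, j] = mat[j, i] = max(ident, 0.0)
    return labels, mat


def classify_duplications(
    nbs_genes: Sequence[GeneModel],
    identity: tuple,
    clusters: Sequence[GeneCluster],
    identity_threshold: float = 0.7,
) -> list[DuplicationEvent]:
    """Call duplicate pairs: each gene's single best partner at identity >=
    threshold; tandem when both members share a cluster, else segmental."""
    labels, mat = identity
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(labels), len(labels)):
        raise ValueError("identity matrix does not match gene labels")
    if not np.allclose(mat, mat.T):
        raise ValueError("identity matrix must be symmetric")
    index = {g: i for i, g in enumerate(labels)}
    for g in nbs_genes:
        if g.gene_id not in index:
            raise ValueError(f"{g.gene_id} missing from identity matrix")
    cluster_of = {}
    for c in clusters:
        for m in c.members:
            cluster_of[m] = c.cluster_id
    pairs = set()
    for g in nbs_genes:
        i = index[g.gene_id]
        row = mat[i].copy()
        row[i] = -1.0
        j = int(np.argmax(row))
        if row[j] >= identity_threshold:
            pairs.add(tuple(sorted((labels[i], labels[j]))))
    events = []
    for a, b in sorted(pairs):
        same_cluster = (
            a in cluster_of and b in cluster_of and cluster_of[a] == cluster_of[b]
        )
        events.append(
            DuplicationEvent(
                gene_a=a,
                gene_b=b,
                kind="tandem" if same_cluster else "segmental",
                identity_fraction=float(mat[index[a], index[b]]),
            )
        )
    return events


def chromosome_summary(
    nbs_genes: Iterable[GeneModel], placed_prefix: str = "chr"
) -> dict:
    """Per-chromosome NBS gene counts; genes on scaffolds (names without the
    placed prefix) are pooled under ``"unplaced"``. Counts sum to the input
    size."""
    counts: dict[str, int] = {}
    for g in nbs_genes:
        key = g.chromosome if g.chromosome.startswith(placed_prefix) else "unplaced"
        counts[key] = counts.get(key, 0) + 1
    return counts
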