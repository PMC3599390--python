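"""Synthetic genomes, gene models and protein families with planted truth.

The generator emulates the statistical structure the downstream analyses
assume: multi-exon NBS-LRR gene models whose proteins carry TIR/CC/RPW8,
NBS and LRR motif content in N->C order, clustered chromosomal placement
with non-NBS filler genes, tandem and segmental duplicate pairs produced by
copy-plus-divergence, intron counts in the observed 0-7 range with defined
phases, and two-family (TIR vs CC) divergence structure for phylogeny.

Determinism: one ``numpy`` generator seeded from the config drives every
choice in a fixed order, so identical config + seed gives byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .architecture import kinase2_diagnostic_index
from .gffio import write_fasta, write_gff3
from .models import GeneModel, TruthRecord
from .motifs import (
    AMINO_ACIDS,
    ConsensusMotif,
    load_paper_motifs,
    synthetic_rpw8_profile,
)

LETTER_CODES = ("TNL", "CNL", "TN", "CN", "N", "NL", "RPW8-NL")

#: architecture counts observed genome-wide in cucumber Gy14 (the default
#: study condition for a 57-gene synthetic genome)
DEFAULT_ARCHITECTURE_COUNTS = {
    "TNL": 11, "CNL": 17, "TN": 2, "CN": 1, "N": 1, "NL": 23, "RPW8-NL": 2,
}

#: N->C planting order of NBS-domain motifs per family context
NBS_ORDER = {
    "CC": ("P-loop", "RNBS-A-nonTIR", "Kinase-2", "RNBS-B", "RNBS-C",
           "CNBS-1", "CNBS-2", "GLPL", "RNBS-D-nonTIR", "MHDV"),
    "TIR": ("P-loop", "RNBS-A-TIR", "Kinase-2", "RNBS-B", "RNBS-C",
            "TNBS-1", "GLPL", "RNBS-D-TIR", "MHDL"),
}
NTERM_ORDER = {"TIR": ("T1", "T2", "T3", "T4"), "CC": ("C1", "C2", "C3")}
LRR_ORDER = ("L1", "L2", "L3")

#: inter-motif spacing inside the compact NBS domain vs between domains (aa)
NBS_LINKER = (2, 8)
DOMAIN_LINKER = (10, 60)

_CODONS = {}


def _codon_table() -> dict:
    """aa -> sorted list of codons (standard genetic code, stops excluded)."""
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        table: dict[str, list] = {}
        for codon, aa in standard_dna_table.forward_table.items():
            table.setdefault(aa, []).append(codon)
        _CODONS.update({aa: sorted(v) for aa, v in table.items()})
    return _CODONS


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at probability ``divergence`` per site (no indels);
    a substituted residue is always different from the original."""
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    if divergence == 0:
        return protein
    out = list(protein)
    hit = rng.random(len(out)) < divergence
    for i in np.flatnonzero(hit):
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def sample_motif_peptide(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    """Draw a peptide from a consensus: constrained positions pick one allowed
    residue, unconstrained positions are uniform random."""
    out = []
    for pos in motif.positions:
        if pos.residues is None:
            out.append(AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
        else:
            choices = sorted(pos.residues)
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    table = _codon_table()
    return "".join(
        table[aa][int(rng.integers(len(table[aa])))] for aa in protein
    )


class _MotifSet:
    """Motif library keyed by (family_context, name), built once."""

    def __init__(self):
        self.by_key = {(m.family_context, m.name): m for m in load_paper_motifs()}
        self.rpw8 = synthetic_rpw8_profile()

    def get(self, context: str, name: str) -> ConsensusMotif:
        if name == "RPW8":
            return self.rpw8
        return self.by_key[(context, name)]


_MOTIFS: list = []


def _motifs() -> _MotifSet:
    if not _MOTIFS:
        _MOTIFS.append(_MotifSet())
    return _MOTIFS[0]


def _family_context(letter_code: str) -> str:
    return "TIR" if letter_code in ("TNL", "TN") else "CC"


def assemble_protein(
    letter_code: str, rng: np.random.Generator
) -> tuple[str, dict, str]:
    """Build a divergence-0 protein for a letter code.

    Returns ``(protein, motif_positions, family_context)`` where
    ``motif_positions`` maps motif name -> start coordinate.
    """
    if letter_code not in LETTER_CODES:
        raise ValueError(f"unknown letter code {letter_code!r}")
    ms = _motifs()
    ctx = _family_context(letter_code)
    plan: list[tuple[str, tuple]] = []  # (motif name, linker range before it)
    if letter_code in ("TNL", "TN"):
        plan += [(n, DOMAIN_LINKER) for n in NTERM_ORDER["TIR"]]
    elif letter_code in ("CNL", "CN"):
        plan += [(n, DOMAIN_LINKER) for n in NTERM_ORDER["CC"]]
    elif letter_code == "RPW8-NL":
        plan += [("RPW8", DOMAIN_LINKER)]
    first_nbs = True
    for n in NBS_ORDER[ctx]:
        plan.append((n, DOMAIN_LINKER if first_nbs else NBS_LINKER))
        first_nbs = False
    if letter_code in ("TNL", "CNL", "NL", "RPW8-NL"):
        first_lrr = True
        for n in LRR_ORDER:
            plan.append((n, DOMAIN_LINKER if first_lrr else NBS_LINKER))
            first_lrr = False
    parts: list[str] = []
    positions: dict[str, int] = {}
    cursor = 0
    for name, (lo, hi) in plan:
        linker = random_protein(int(rng.integers(lo, hi + 1)), rng)
        parts.append(linker)
        cursor += len(linker)
        pep = sample_motif_peptide(ms.get(ctx, name), rng)
        positions[name] = cursor
        parts.append(pep)
        cursor += len(pep)
    tail = random_protein(int(rng.integers(*DOMAIN_LINKER)), rng)
    parts.append(tail)
    return "".join(parts), positions, ctx


def _choose_intron_sites(
    cds_len: int,
    n: int,
    rng: np.random.Generator,
    min_exon: int = 20,
    phase_probs=None,
) -> list[int]:
    """n distinct CDS split points, each >= min_exon from the ends and from
    each other; optionally biased to hit a target phase distribution."""
    if n == 0:
        return []
    if cds_len < (n + 1) * min_exon:
        raise ValueError(f"cannot place {n} introns in a {cds_len} nt CDS")
    for _ in range(200):
        sites = np.sort(
            rng.choice(np.arange(min_exon, cds_len - min_exon), size=n, replace=False)
        )
        if phase_probs is not None:
            phases = rng.choice(3, size=n, p=phase_probs)
            sites = sites - (sites % 3) + phases
            sites = np.sort(np.clip(sites, min_exon, cds_len - min_exon))
        if all(b - a >= min_exon for a, b in zip(sites, sites[1:])):
            return [int(s) for s in sites]
    raise ValueError("failed to place introns")


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_gene_model(
    protein: str,
    intron_count: int,
    rng: np.random.Generator,
    gene_id: str = "gene1",
    chromosome: str = "chrU",
    strand: str = "+",
    is_nbs: bool = True,
    phase_probs=None,
) -> tuple[GeneModel, str, tuple]:
    """Reverse-translate, insert introns, and return ``(model, region,
    intron_phases)``. Exon coordinates are relative to the region start."""
    if not 0 <= intron_count <= 7:
        raise ValueError("intron count must be in [0, 7]")
    cds = reverse_translate(protein, rng) + "TAA"
    sites = _choose_intron_sites(len(cds), intron_count, rng, phase_probs=phase_probs)
    phases = tuple(s % 3 for s in sites)
    pieces = []
    bounds = [0] + sites + [len(cds)]
    for a, b in zip(bounds, bounds[1:]):
        pieces.append(cds[a:b])
    region_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cursor = 0
    for i, piece in enumerate(pieces):
        exons.append((cursor, cursor + len(piece)))
        region_parts.append(piece)
        cursor += len(piece)
        if i < len(pieces) - 1:
            intron = "GT" + _random_dna(int(rng.integers(60, 200)), rng) + "AG"
            region_parts.append(intron)
            cursor += len(intron)
    region = "".join(region_parts)
    if strand == "-":
        n = len(region)
        region = str(Seq(region).reverse_complement())
        exons = sorted((n - e, n - s) for s, e in exons)
    model = GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        strand=strand,
        exons=exons,
        cds=cds,
        protein=protein,
        is_nbs=is_nbs,
    )
    return model, region, phases


def _realized_kinase2_residue(protein: str, positions: dict, ctx: str) -> str | None:
    if "Kinase-2" not in positions:
        return None
    motif = _motifs().get(ctx, "Kinase-2")
    return protein[positions["Kinase-2"] + kinase2_diagnostic_index(motif)]


def generate_gene(
    letter_code: str,
    intron_count: int,
    divergence: float,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    gene_id: str = "gene1",
    chromosome: str = "chrU",
    strand: str = "+",
    phase_probs=None,
) -> tuple[GeneModel, TruthRecord, str]:
    """Generate one synthetic NBS-LRR gene.

    Returns ``(gene_model, truth, region_sequence)``; exon coordinates are
    relative to the region start (``generate_genome`` shifts them into
    chromosome coordinates).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    protein, positions, ctx = assemble_protein(letter_code, rng)
    protein = mutate_protein(protein, divergence, rng)
    model, region, phases = build_gene_model(
        protein, intron_count, rng, gene_id=gene_id, chromosome=chromosome,
        strand=strand, is_nbs=True, phase_probs=phase_probs,
    )
    truth = TruthRecord(
        gene_id=gene_id,
        planted_letter_code=letter_code,
        planted_family=ctx,
        planted_motif_positions=positions,
        kinase2_residue=_realized_kinase2_residue(protein, positions, ctx),
        intron_count=intron_count,
        intron_phases=phases,
    )
    return model, truth, region


def generate_filler_gene(
    rng: np.random.Generator, gene_id: str, chromosome: str = "chrU"
) -> tuple[GeneModel, TruthRecord, str]:
    """Short single-exon gene with no NBS motif content (cluster-rule filler)."""
    protein = random_protein(int(rng.integers(60, 121)), rng)
    strand = "+" if rng.random() < 0.5 else "-"
    model, region, _ = build_gene_model(
        protein, 0, rng, gene_id=gene_id, chromosome=chromosome, strand=strand,
        is_nbs=False,
    )
    truth = TruthRecord(
        gene_id=gene_id, planted_letter_code="filler", planted_family="none"
    )
    return model, truth, region


@dataclass
class ClusterSpec:
    chromosome: int  # 0-based chromosome index
    n_members: int
    max_span_bases: int
    n_intervening_non_nbs: int


@dataclass
class DuplicationSpec:
    kind: str  # "tandem" | "segmental"
    cluster_index: int | None = None  # tandem: which cluster hosts the pair

    def __post_init__(self):
        if self.kind not in ("tandem", "segmental"):
            raise ValueError(f"bad duplication kind {self.kind!r}")
        if self.kind == "tandem" and self.cluster_index is None:
            raise ValueError("tandem duplication needs a cluster_index")


def default_cluster_spec() -> list:
    """Nine clusters totalling 33 genes (largest 10, smallest 2) spread over
    the seven chromosomes, mirroring the observed genome-wide clustering."""
    sizes = [10, 5, 4, 3, 3, 2, 2, 2, 2]
    chroms = [1, 4, 0, 2, 5, 1, 1, 6, 3]
    return [
        ClusterSpec(c, n, max_span_bases=150_000, n_intervening_non_nbs=2)
        for c, n in zip(chroms, sizes)
    ]


def default_duplication_spec() -> list:
    """Seven tandem plus four segmental duplicate pairs."""
    return [DuplicationSpec("tandem", i) for i in range(7)] + [
        DuplicationSpec("segmental") for _ in range(4)
    ]


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 7
    chromosome_length: int = 1_200_000
    n_genes_per_architecture: dict = field(
        default_factory=lambda: dict(DEFAULT_ARCHITECTURE_COUNTS)
    )
    cluster_spec: list = field(default_factory=default_cluster_spec)
    duplication_spec: list = field(default_factory=default_duplication_spec)
    intron_range: tuple = (0, 7)
    intron_phase_probs: tuple | None = None
    divergence: float = 0.0
    pair_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.n_genes_per_architecture.values()):
            raise ValueError("architecture counts must be non-negative")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        lo, hi = self.intron_range
        if not (0 <= lo <= hi <= 7):
            raise ValueError("intron range must lie in [0, 7]")
        for cs in self.cluster_spec:
            if cs.chromosome >= self.n_chromosomes:
                raise ValueError("cluster spec references a missing chromosome")
            if cs.max_span_bases >= self.chromosome_length:
                raise ValueError("cluster span exceeds chromosome length")
        n_cluster = sum(cs.n_members for cs in self.cluster_spec)
        if n_cluster > sum(self.n_genes_per_architecture.values()):
            raise ValueError("cluster spec needs more genes than are generated")

    @property
    def total_genes(self) -> int:
        return sum(self.n_genes_per_architecture.values())


@dataclass
class SyntheticGenome:
    chromosomes: dict
    genes: list
    truth: dict
    config: SyntheticConfig

    @property
    def nbs_genes(self) -> list:
        return [g for g in self.genes if g.is_nbs]

    def proteins(self) -> dict:
        return {g.gene_id: g.protein for g in self.nbs_genes}

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "proteins": outdir / "proteins.fa",
            "cds": outdir / "cds.fa",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.chromosomes, paths["genome"])
        write_gff3(self.genes, paths["gff3"])
        write_fasta({g.gene_id: g.protein for g in self.genes}, paths["proteins"])
        write_fasta({g.gene_id: g.cds for g in self.genes}, paths["cds"])
        rows = ["\t".join([
            "gene_id", "letter_code", "family", "cluster_id", "duplication_partner",
            "kinase2_residue", "intron_count", "intron_phases", "motif_positions",
        ])]
        for g in self.genes:
            t = self.truth[g.gene_id]
            motif_pos = ";".join(f"{k}:{v}" for k, v in t.planted_motif_positions.items())
            rows.append("\t".join([
                t.gene_id, t.planted_letter_code, t.planted_family,
                t.cluster_id or ".", t.duplication_partner or ".",
                t.kinase2_residue or ".", str(t.intron_count),
                ",".join(map(str, t.intron_phases)) or ".", motif_pos or ".",
            ]))
        paths["truth"].write_text("\n".join(rows) + "\n")
        return paths


def generate_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Generate a genome per the config: clustered and singleton NBS genes,
    filler genes, and planted tandem/segmental duplicate pairs."""
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    codes: list[str] = []
    for code in LETTER_CODES:  # fixed order for determinism
        codes += [code] * config.n_genes_per_architecture.get(code, 0)
    order = rng.permutation(len(codes))
    codes = [codes[i] for i in order]

    lo, hi = config.intron_range
    next_id = [0]
    next_fill = [0]

    def new_gene(code: str, chromosome: str, source=None):
        gid = f"synt{next_id[0]:03d}"
        next_id[0] += 1
        strand = "+" if rng.random() < 0.5 else "-"
        n_introns = int(rng.integers(lo, hi + 1))
        if source is None:
            model, truth, region = generate_gene(
                code, n_introns, config.divergence, rng=rng, gene_id=gid,
                chromosome=chromosome, strand=strand,
                phase_probs=config.intron_phase_probs,
            )
        else:  # copy-plus-divergence duplicate of an existing gene
            src_model, src_truth = source
            protein = mutate_protein(src_model.protein, config.pair_divergence, rng)
            model, region, phases = build_gene_model(
                protein, n_introns, rng, gene_id=gid, chromosome=chromosome,
                strand=strand, is_nbs=True, phase_probs=config.intron_phase_probs,
            )
            truth = TruthRecord(
                gene_id=gid,
                planted_letter_code=src_truth.planted_letter_code,
                planted_family=src_truth.planted_family,
                planted_motif_positions=dict(src_truth.planted_motif_positions),
                kinase2_residue=_realized_kinase2_residue(
                    protein, src_truth.planted_motif_positions, src_truth.planted_family
                ),
                intron_count=n_introns,
                intron_phases=phases,
            )
        return model, truth, region

    def new_filler(chromosome: str):
        gid = f"fill{next_fill[0]:03d}"
        next_fill[0] += 1
        return generate_filler_gene(rng, gid, chromosome)

    placements: list[tuple[str, int, GeneModel, TruthRecord, str]] = []
    cursors = {c: 10_000 for c in chrom_names}

    def place(chromosome: str, offset: int, gene_pack):
        model, truth, region = gene_pack
        placements.append((chromosome, offset, model, truth, region))
        return offset + len(region)

    def place_break_fillers(chromosome: str, n: int = 9):
        for _ in range(n):
            end = place(chromosome, cursors[chromosome], new_filler(chromosome))
            cursors[chromosome] = end + int(rng.integers(300, 800))

    # clusters first, consuming codes from the front of the shuffled pool
    pool = iter(codes)
    tandem_clusters = {
        d.cluster_index for d in config.duplication_spec if d.kind == "tandem"
    }
    n_segmental = sum(1 for d in config.duplication_spec if d.kind == "segmental")
    for ci, cs in enumerate(config.cluster_spec):
        if cs.n_members < 2:
            raise ValueError("clusters need >= 2 members")
        chrom = chrom_names[cs.chromosome]
        cluster_id = f"cluster{ci + 1}"
        gap = cs.max_span_bases // max(cs.n_members - 1, 1)
        start = cursors[chrom]
        if start + cs.max_span_bases + 50_000 > config.chromosome_length:
            raise ValueError(
                f"cluster {cluster_id} does not fit on {chrom}: spec infeasible"
            )
        members: list[tuple[GeneModel, TruthRecord]] = []
        for mi in range(cs.n_members):
            if ci in tandem_clusters and mi == 1:
                pack = new_gene(members[0][1].planted_letter_code, chrom,
                                source=members[0])
                pack[1].duplication_partner = members[0][0].gene_id
                members[0][1].duplication_partner = pack[0].gene_id
                next(pool)  # the copy replaces one fresh gene from the pool
            else:
                pack = new_gene(next(pool), chrom)
            model, truth, region = pack
            truth.cluster_id = cluster_id
            offset = start + mi * gap
            if len(region) >= gap:
                raise ValueError("planted gene spans overlap: spec infeasible")
            place(chrom, offset, pack)
            members.append((model, truth))
            if mi < cs.n_members - 1:  # intervening non-NBS fillers
                for fi in range(cs.n_intervening_non_nbs):
                    foff = (
                        offset
                        + len(region)
                        + 200
                        + fi * max((gap - len(region) - 2_000)
                                   // max(cs.n_intervening_non_nbs, 1), 700)
                    )
                    place(chrom, foff, new_filler(chrom))
        cursors[chrom] = start + cs.max_span_bases + len(region) + 5_000
        place_break_fillers(chrom)

    # singletons round-robin; segmental pairs get copies on other chromosomes
    singles = list(pool)
    if n_segmental > max(len(singles) - n_segmental, 0):
        raise ValueError("not enough singleton genes for the segmental pairs")
    # each segmental copy replaces one fresh gene so the total count holds
    singles = singles[: len(singles) - n_segmental]
    seg_sources: list[tuple[GeneModel, TruthRecord, str]] = []
    rr = 0
    for k, code in enumerate(singles):
        chrom = chrom_names[rr % len(chrom_names)]
        rr += 1
        if len(seg_sources) < n_segmental:
            pack = new_gene(code, chrom)
            seg_sources.append((pack[0], pack[1], chrom))
        else:
            pack = new_gene(code, chrom)
        end = place(chrom, cursors[chrom], pack)
        cursors[chrom] = end + int(rng.integers(2_000, 5_000))
        place_break_fillers(chrom)
    for src_model, src_truth, src_chrom in seg_sources:
        others = [c for c in chrom_names if c != src_chrom]
        chrom = others[int(rng.integers(len(others)))]
        pack = new_gene(src_truth.planted_letter_code, chrom,
                        source=(src_model, src_truth))
        pack[1].duplication_partner = src_model.gene_id
        src_truth.duplication_partner = pack[0].gene_id
        end = place(chrom, cursors[chrom], pack)
        cursors[chrom] = end + int(rng.integers(2_000, 5_000))
        place_break_fillers(chrom)

    for chrom, cur in cursors.items():
        if cur > config.chromosome_length:
            raise ValueError(f"{chrom}: placements exceed chromosome length")

    # assemble chromosome sequences: random background + planted regions
    chromosomes: dict[str, str] = {}
    buffers = {
        c: np.array(list("ACGT"))[rng.integers(0, 4, size=config.chromosome_length)]
        for c in chrom_names
    }
    spans: dict[str, list] = {c: [] for c in chrom_names}
    for chrom, offset, model, truth, region in placements:
        for s, e in spans[chrom]:
            if offset < e and offset + len(region) > s:
                raise ValueError("planted gene spans overlap: spec infeasible")
        spans[chrom].append((offset, offset + len(region)))
        buffers[chrom][offset : offset + len(region)] = list(region)
    for c in chrom_names:
        chromosomes[c] = "".join(buffers[c])

    genes: list[GeneModel] = []
    truth: dict[str, TruthRecord] = {}
    for chrom, offset, model, t, region in placements:
        model.exons = [(s + offset, e + offset) for s, e in model.exons]
        genes.append(model)
        truth[model.gene_id] = t
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return SyntheticGenome(chromosomes=chromosomes, genes=genes, truth=truth,
                           config=config)


def generate_family_set(
    n_tir: int,
    n_cc: int,
    within_divergence: float,
    between_divergence: float | None,
    seed: int = 0,
    core_length: int = 200,
) -> tuple[dict, dict]:
    """Two protein families descended from a common random core.

    Family ancestors are mutated copies of a shared root (about
    ``between_divergence`` apart); members are mutated copies of their
    ancestor (``within_divergence``). Returns ``(sequences, family_labels)``.
    """
    if n_tir > 0 and n_cc > 0:
        if between_divergence is None or between_divergence <= within_divergence:
            raise ValueError("between_divergence must exceed within_divergence")
    rng = np.random.default_rng(seed)
    root = random_protein(core_length, rng)
    b = 0.0 if between_divergence is None else between_divergence / 2
    ancestors = {
        "TIR": mutate_protein(root, b, rng),
        "CC": mutate_protein(root, b, rng),
    }
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for fam, n in (("TIR", n_tir), ("CC", n_cc)):
        for i in range(n):
            name = f"{fam}_{i + 1:02d}"
            seqs[name] = mutate_protein(ancestors[fam], within_divergence, rng)
            labels[name] = fam
    return seqs, labels


def generate_pcr_templates(
    n_loci: int = 10,
    n_pseudogenes: int = 2,
    seed: int = 0,
    family_context: str = "CC",
    flank_range: tuple = (200, 600),
) -> tuple[dict, list]:
    """Intronless NBS loci embedded in random flanks for in-silico PCR tests.

    The first ``n_loci - n_pseudogenes`` loci are clean; the remainder carry
    an in-frame internal stop codon planted between the P-loop and GLPL.
    Returns ``(templates, truth_rows)``.
    """
    if n_pseudogenes > n_loci:
        raise ValueError("n_pseudogenes exceeds n_loci")
    rng = np.random.default_rng(seed)
    code = "N" if family_context == "CC" else "TN"
    templates: dict[str, str] = {}
    rows: list[dict] = []
    for k in range(n_loci):
        protein, positions, ctx = assemble_protein(code, rng)
        cds = reverse_translate(protein, rng) + "TAA"
        pseudo = k >= n_loci - n_pseudogenes
        if pseudo:
            ploop_end = positions["P-loop"] + _motifs().get(ctx, "P-loop").length
            glpl_start = positions["GLPL"]
            aa_idx = (ploop_end + glpl_start) // 2
            cds = cds[: aa_idx * 3] + "TAA" + cds[aa_idx * 3 + 3 :]
        left = _random_dna(int(rng.integers(*flank_range)), rng)
        right = _random_dna(int(rng.integers(*flank_range)), rng)
        tid = f"locus{k + 1:02d}"
        templates[tid] = left + cds + right
        rows.append(
            {
                "template_id": tid,
                "cds_offset": len(left),
                "pseudogene": pseudo,
                "family_context": ctx,
                "motif_positions": positions,
            }
        )
    return templates, rows
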