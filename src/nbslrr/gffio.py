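"""FASTA / GFF3 input-output and splice-translate helpers.

GFF3 files are 1-based inclusive with gene/mRNA/exon/CDS features and a CDS
phase column; internal coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel


def write_fasta(records: dict, path) -> None:
    """Write an id -> sequence mapping as FASTA (insertion order preserved)."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def gff3_phase(cds_lengths_upstream: int) -> int:
    """GFF3 CDS phase: bases to skip at feature start to reach a codon start."""
    return (3 - cds_lengths_upstream % 3) % 3


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};is_nbs={'1' if g.is_nbs else '0'}"
        lines.append(
            "\t".join(
                [g.chromosome, "nbslrr", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", attrs]
            )
        )
        mrna_id = f"{g.gene_id}.mRNA"
        lines.append(
            "\t".join(
                [g.chromosome, "nbslrr", "mRNA", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={mrna_id};Parent={g.gene_id}"]
            )
        )
        coding_order = g.exons[::-1] if g.strand == "-" else g.exons
        cum = 0
        phases = {}
        for s, e in coding_order:
            phases[(s, e)] = gff3_phase(cum)
            cum += e - s
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [g.chromosome, "nbslrr", "exon", str(s + 1), str(e), ".",
                     g.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}"]
                )
            )
            lines.append(
                "\t".join(
                    [g.chromosome, "nbslrr", "CDS", str(s + 1), str(e), ".",
                     g.strand, str(phases[(s, e)]), f"ID={mrna_id}.cds{i};Parent={mrna_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path, genome: dict | None = None) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` records.

    When ``genome`` (id -> sequence) is supplied, the CDS and protein of each
    gene are reconstructed by splicing and translating.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = []
        for cds in db.children(gene, featuretype="CDS", order_by="start"):
            exons.append((cds.start - 1, cds.end))
        if not exons:
            raise ValueError(f"{gene.id}: gene without CDS features")
        model = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            exons=exons,
            is_nbs=gene.attributes.get("is_nbs", ["0"])[0] == "1",
        )
        if genome is not None:
            model.cds = splice_cds(genome, model)
            model.protein = translate_cds(model.cds)
        genes.append(model)
    return genes


def splice_cds(genome: dict, gene: GeneModel) -> str:
    chrom = genome[gene.chromosome]
    parts = [chrom[s:e] for s, e in gene.exons]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def translate_cds(cds: str) -> str:
    protein = str(Seq(cds).translate())
    return protein[:-1] if protein.endswith("*") else protein
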