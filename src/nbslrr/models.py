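"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """A protein-coding gene model.

    Coordinates are 0-based half-open on the forward genomic strand
    (GFF3 I/O converts to/from 1-based inclusive). ``exons`` are CDS exons
    sorted by genomic coordinate; for minus-strand genes the coding order is
    the reverse of the stored order.
    """

    gene_id: str
    chromosome: str
    strand: str  # "+" | "-"
    exons: list  # [(start, end), ...] genomic order, non-overlapping
    cds: str = ""  # spliced CDS in coding orientation
    protein: str = ""
    is_nbs: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def coding_exon_lengths(self) -> list:
        lengths = [e - s for s, e in self.exons]
        return lengths[::-1] if self.strand == "-" else lengths


@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic gene."""

    gene_id: str
    planted_letter_code: str
    planted_family: str  # "TIR" | "CC" | "none"
    planted_motif_positions: dict = field(default_factory=dict)
    cluster_id: str | None = None
    duplication_partner: str | None = None
    kinase2_residue: str | None = None  # realized diagnostic residue (post-divergence)
    intron_count: int = 0
    intron_phases: tuple = ()
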