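"""In-silico degenerate PCR on nucleotide templates.

Primers are written 5'->3' over the IUPAC nucleotide alphabet. The forward
primer anneals to the minus strand (so its sequence appears on the plus
strand) and the reverse primer anneals to the plus strand (so its reverse
complement appears on the plus strand, downstream). Both orientations are
considered: the reverse primer may also act as the left-hand primer on the
plus strand with the forward primer priming the minus strand, producing a
minus-strand amplicon. Every compatible, non-overlapping placement pair
whose product length falls inside the size window is reported; wet-lab
competition between overlapping products is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .architecture import extract_nbs_core, screen_pseudogenes
from .motifs import ConsensusMotif, load_paper_motifs, scan_sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str  # 5'->3' as supplied

    def __post_init__(self):
        for seq in (self.forward, self.reverse):
            for c in seq.upper():
                if c not in IUPAC:
                    raise ValueError(f"{self.name}: non-IUPAC character {c!r}")


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    strand: str  # "+": forward primer on plus strand; "-": the converse
    start: int  # 0-based half-open on the plus strand
    end: int
    sequence: str  # in primer orientation (starts with the left primer site)

    @property
    def length(self) -> int:
        return self.end - self.start


def revcomp_iupac(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def iupac_match(primer: str, site: str, max_mismatch: int = 0) -> bool:
    """True iff every primer symbol's degeneracy set contains the template
    base, allowing up to ``max_mismatch`` violations."""
    if len(primer) != len(site):
        raise ValueError("primer and site lengths differ")
    mismatches = 0
    for p, s in zip(primer.upper(), site.upper()):
        try:
            allowed = IUPAC[p]
        except KeyError:
            raise ValueError(f"non-IUPAC primer character {p!r}") from None
        if s not in allowed:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def find_sites(template: str, primer: str, max_mismatch: int = 0) -> list[int]:
    """All start positions where the primer pattern matches the plus strand."""
    primer = primer.upper()
    template = template.upper()
    k = len(primer)
    if k == 0 or k > len(template):
        return []
    tarr = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    enc = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        enc[ord(b)] = i
    tidx = enc[tarr]
    allowed = np.zeros((k, 4), dtype=bool)
    for i, p in enumerate(primer):
        if p not in IUPAC:
            raise ValueError(f"non-IUPAC primer character {p!r}")
        for b in IUPAC[p]:
            allowed[i, _BASE_INDEX[b]] = True
    windows = np.lib.stride_tricks.sliding_window_view(tidx, k)
    valid = windows >= 0
    match = np.zeros_like(valid)
    match[valid] = allowed[np.broadcast_to(np.arange(k), windows.shape)[valid],
                           windows[valid]]
    mism = k - match.sum(axis=1)
    return [int(i) for i in np.flatnonzero(mism <= max_mismatch)]


def amplify(
    template: str,
    primer_pair: PrimerPair,
    size_window: tuple = (300, 800),
    max_mismatch: int = 0,
    template_id: str = "template",
) -> list[Amplicon]:
    """Enumerate all amplicons of a primer pair on one template.

    Products are reported sorted by (start, length). Primer footprints must
    not overlap.
    """
    lo, hi = size_window
    if lo > hi:
        raise ValueError("size window inverted")
    template = template.upper()
    out: list[Amplicon] = []
    fwd, rev = primer_pair.forward.upper(), primer_pair.reverse.upper()
    for strand, left, right in (("+", fwd, rev), ("-", rev, fwd)):
        left_sites = find_sites(template, left, max_mismatch)
        right_sites = find_sites(template, revcomp_iupac(right), max_mismatch)
        for i in left_sites:
            for j in right_sites:
                if j < i + len(left):
                    continue
                end = j + len(right)
                length = end - i
                if lo <= length <= hi:
                    seq = template[i:end]
                    if strand == "-":
                        seq = revcomp_iupac(seq)
                    out.append(
                        Amplicon(template_id, strand, i, end, seq)
                    )
    out.sort(key=lambda a: (a.start, a.length, a.strand))
    return out


# ---------------------------------------------------------------------------
# degenerate primer construction from protein consensus motifs

_AA_DEGENERATE: dict = {}


def _degenerate_codon(residues: Iterable[str]) -> str:
    """IUPAC codon covering every codon of every residue in the set."""
    from Bio.Data.CodonTable import standard_dna_table

    key = frozenset(residues)
    if key not in _AA_DEGENERATE:
        codons = [
            c for c, aa in standard_dna_table.forward_table.items() if aa in key
        ]
        cols = []
        for i in range(3):
            bases = frozenset(c[i] for c in codons)
            sym = next(s for s, b in IUPAC.items() if frozenset(b) == bases)
            cols.append(sym)
        _AA_DEGENERATE[key] = "".join(cols)
    return _AA_DEGENERATE[key]


def primer_from_motif(motif: ConsensusMotif, start: int, n_positions: int) -> str:
    """Degenerate DNA primer covering motif positions [start, start+n).

    Unconstrained positions become NNN; constrained positions expand to the
    IUPAC union of all synonymous codons of their allowed residues.
    """
    if start < 0 or start + n_positions > motif.length:
        raise ValueError("primer window outside motif")
    parts = []
    for pos in motif.positions[start : start + n_positions]:
        parts.append("NNN" if pos.residues is None else _degenerate_codon(pos.residues))
    return "".join(parts)


def default_primer_pairs() -> list[PrimerPair]:
    """Three degenerate primer pairs anchored on the P-loop (forward) and
    GLPL (reverse) consensus motifs.

    These are synthetic surrogates constructed from the bundled consensus
    library (the published primer sequences live in a supplement that is not
    transcribed here); they are guaranteed to amplify the synthetic NBS loci
    of :mod:`nbslrr.synthetic`.
    """
    lib = {(m.family_context, m.name): m for m in load_paper_motifs()}
    cc_ploop = lib[("CC", "P-loop")]
    cc_glpl = lib[("CC", "GLPL")]
    tir_ploop = lib[("TIR", "P-loop")]
    tir_glpl = lib[("TIR", "GLPL")]
    # forward primers start at P-loop position 0 and reverse primers run
    # through the final GLPL position, so an amplicon translated in the
    # primer-anchored frame contains both full motif windows
    pairs = [
        PrimerPair(
            "ccNBS-1",
            primer_from_motif(cc_ploop, 0, 14),
            revcomp_iupac(primer_from_motif(cc_glpl, 8, 13)),
        ),
        PrimerPair(
            "tirNBS-1",
            primer_from_motif(tir_ploop, 0, 12),
            revcomp_iupac(primer_from_motif(tir_glpl, 8, 13)),
        ),
        PrimerPair(
            "ccNBS-2",
            primer_from_motif(cc_ploop, 0, 10),
            revcomp_iupac(primer_from_motif(cc_glpl, 6, 15)),
        ),
    ]
    return pairs


# ---------------------------------------------------------------------------
# survey


def pcr_survey(
    genome: dict,
    primer_pairs: Sequence[PrimerPair],
    size_window: tuple = (300, 800),
    max_mismatch: int = 0,
    motif_threshold: float = 0.6,
) -> pd.DataFrame:
    """Candidate-RGH discovery: amplify, translate in the primer-anchored
    frame, drop internal-stop (pseudogene) products, and retain fragments
    whose translation carries an ordered P-loop..GLPL core.

    Returns one row per amplicon with its provenance and screening status
    (``retained`` / ``pseudogene`` / ``no_core``).
    """
    library = load_paper_motifs()
    rows: list[dict] = []
    for template_id in genome:
        for pair in primer_pairs:
            for amp in amplify(
                genome[template_id], pair, size_window, max_mismatch,
                template_id=template_id,
            ):
                orf = amp.sequence[: len(amp.sequence) - len(amp.sequence) % 3]
                status = screen_pseudogenes(orf)
                protein = _translate(orf)
                if status == "clean":
                    hits = scan_sequence(protein, library, threshold=motif_threshold)
                    core = extract_nbs_core(protein, hits)
                    status = "retained" if core is not None else "no_core"
                rows.append(
                    {
                        "template_id": template_id,
                        "primer_pair": pair.name,
                        "strand": amp.strand,
                        "start": amp.start,
                        "end": amp.end,
                        "length": amp.length,
                        "status": status,
                        "translation": protein,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "template_id", "primer_pair", "strand", "start", "end", "length",
            "status", "translation",
        ],
    )


def _translate(orf: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(orf).translate())
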