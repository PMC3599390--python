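"""Degenerate protein consensus motifs: parsing, scoring, and scanning.

Motif consensus strings use a three-level conservation alphabet common in
published motif tables for NBS-LRR proteins:

* uppercase letter  -- conserved position (weight 1.0),
* lowercase letter  -- weakly conserved position (weight 0.5),
* ``x`` / ``X``     -- unconstrained position (weight 0.0, matches anything),
* ``a/b``           -- one position admitting either residue; the weight is
  taken from the case of the first letter (left-greedy pairing).

A window is scored as the weighted fraction of constrained positions whose
residue falls in the allowed set; the score is therefore in [0, 1] and a
perfect consensus match scores 1.0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CONSERVED_WEIGHT = 1.0
WEAK_WEIGHT = 0.5

_FIXTURE = "motifs_cc_tir.tsv"


@dataclass(frozen=True)
class MotifPosition:
    """One column of a consensus motif.

    ``residues`` is ``None`` for an unconstrained ("any") position.
    """

    residues: frozenset | None
    weight: float


@dataclass
class ConsensusMotif:
    name: str
    family_context: str  # "CC" | "TIR" | "shared"
    region: str  # "N-terminal" | "NBS" | "LRR&C-terminal"
    positions: tuple
    source: str = ""
    printed_length: int | None = None
    _allowed: np.ndarray | None = field(default=None, repr=False, compare=False)
    _weights: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def weight_sum(self) -> float:
        return float(sum(p.weight for p in self.positions))

    def _tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (length, 26) allowed-residue table and per-position weights."""
        if self._allowed is None:
            allowed = np.zeros((self.length, 26), dtype=bool)
            weights = np.zeros(self.length, dtype=float)
            for i, pos in enumerate(self.positions):
                weights[i] = pos.weight
                if pos.residues is None:
                    allowed[i, :] = True
                else:
                    for aa in pos.residues:
                        allowed[i, ord(aa) - 65] = True
            object.__setattr__(self, "_allowed", allowed)
            object.__setattr__(self, "_weights", weights)
        return self._allowed, self._weights


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring placement of a motif on a protein (0-based, half-open)."""

    motif_name: str
    family_context: str
    start: int
    end: int
    raw_score: float
    normalized_score: float


class MotifParseError(ValueError):
    pass


def parse_consensus(
    raw_text: str,
    name: str,
    family_context: str = "shared",
    region: str = "NBS",
    source: str = "",
    printed_length: int | None = None,
) -> ConsensusMotif:
    """Parse a degenerate consensus string into a :class:`ConsensusMotif`.

    Raises :class:`MotifParseError` on a dangling ``/`` or an illegal
    character.
    """
    text = raw_text.strip()
    if not text:
        raise MotifParseError(f"{name}: empty consensus")
    if text.startswith("/") or text.endswith("/"):
        raise MotifParseError(f"{name}: dangling '/' at string boundary")
    positions: list[MotifPosition] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "/":
            raise MotifParseError(f"{name}: unexpected '/' at index {i}")
        if not c.isalpha():
            raise MotifParseError(f"{name}: illegal character {c!r} at index {i}")
        pair = None
        if i + 1 < len(text) and text[i + 1] == "/":
            if i + 2 >= len(text) or not text[i + 2].isalpha():
                raise MotifParseError(f"{name}: dangling '/' at index {i + 1}")
            pair = text[i + 2]
            i += 3
        else:
            i += 1
        if c in ("x", "X"):
            # an x/y pair makes no sense; treat x as fully unconstrained
            positions.append(MotifPosition(None, 0.0))
            continue
        weight = CONSERVED_WEIGHT if c.isupper() else WEAK_WEIGHT
        residues = {c.upper()}
        if pair is not None and pair not in ("x", "X"):
            residues.add(pair.upper())
        for aa in residues:
            if aa not in AMINO_ACIDS:
                raise MotifParseError(f"{name}: {aa!r} is not an amino acid")
        positions.append(MotifPosition(frozenset(residues), weight))
    return ConsensusMotif(
        name=name,
        family_context=family_context,
        region=region,
        positions=tuple(positions),
        source=source,
        printed_length=printed_length,
    )


def load_paper_motifs() -> list[ConsensusMotif]:
    """Load the bundled 40-motif consensus library (20 CC-context + 20
    TIR-context motifs covering the N-terminal, NBS and LRR/C-terminal
    regions)."""
    motifs: list[ConsensusMotif] = []
    path = resources.files("nbslrr.data").joinpath(_FIXTURE)
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            motifs.append(
                parse_consensus(
                    row["consensus"],
                    name=row["name"],
                    family_context=row["family_context"],
                    region=row["region"],
                    source=row["motif_number"],
                    printed_length=int(row["printed_length"]),
                )
            )
    if len(motifs) != 40:
        raise RuntimeError(f"motif fixture corrupt: {len(motifs)} rows, expected 40")
    return motifs


def motif_conformance_report(motifs: Iterable[ConsensusMotif] | None = None):
    """Compare parsed position counts against the table's printed lengths.

    Returns a list of dicts with keys ``family_context, name, parsed_length,
    printed_length, conforms``.
    """
    if motifs is None:
        motifs = load_paper_motifs()
    report = []
    for m in motifs:
        report.append(
            {
                "family_context": m.family_context,
                "name": m.name,
                "parsed_length": m.length,
                "printed_length": m.printed_length,
                "conforms": m.printed_length is not None and m.length == m.printed_length,
            }
        )
    return report


def encode_protein(protein: str) -> np.ndarray:
    """Map a protein string onto 0..25 indices (A=0 .. Z=25).

    Non-alphabetic characters are rejected; unusual letters (B, J, O, U, Z,
    X) are representable and simply never match a constrained position.
    """
    arr = np.frombuffer(protein.upper().encode("ascii"), dtype=np.uint8).astype(np.int64) - 65
    if arr.size and (arr.min() < 0 or arr.max() > 25):
        raise ValueError("protein contains non-alphabetic characters")
    return arr


def score_window(motif: ConsensusMotif, peptide_window: str) -> float:
    """Normalized weighted-consensus score of one window (length must equal
    the motif length). A motif with zero total weight scores 1.0 by
    convention (it constrains nothing)."""
    if len(peptide_window) != motif.length:
        raise ValueError(
            f"window length {len(peptide_window)} != motif length {motif.length}"
        )
    allowed, weights = motif._tables()
    idx = encode_protein(peptide_window)
    raw = float((allowed[np.arange(motif.length), idx] * weights).sum())
    wsum = motif.weight_sum
    return raw / wsum if wsum > 0 else 1.0


def scan_sequence(
    protein: str,
    motif_library: Sequence[ConsensusMotif],
    threshold: float = 0.6,
) -> list[MotifHit]:
    """Report, per motif, its best-scoring window with normalized score >=
    ``threshold`` (at most one hit per motif; ties broken by leftmost start).
    """
    if not protein:
        raise ValueError("empty protein")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    seq = encode_protein(protein)
    hits: list[MotifHit] = []
    for motif in motif_library:
        L = motif.length
        if L > seq.size:
            continue
        allowed, weights = motif._tables()
        windows = np.lib.stride_tricks.sliding_window_view(seq, L)
        match = allowed[np.arange(L), windows]
        raw = match @ weights
        wsum = motif.weight_sum
        norm = raw / wsum if wsum > 0 else np.ones_like(raw)
        best = int(np.argmax(norm))  # argmax returns the leftmost maximum
        if norm[best] >= threshold:
            hits.append(
                MotifHit(
                    motif_name=motif.name,
                    family_context=motif.family_context,
                    start=best,
                    end=best + L,
                    raw_score=float(raw[best]),
                    normalized_score=float(norm[best]),
                )
            )
    return hits


def hits_to_rows(hits: Iterable[MotifHit]) -> list[dict]:
    return [
        {
            "motif_name": h.motif_name,
            "family_context": h.family_context,
            "start": h.start,
            "end": h.end,
            "raw_score": h.raw_score,
            "normalized_score": h.normalized_score,
        }
        for h in hits
    ]


# A synthetic stand-in for an N-terminal RPW8-like profile. No published
# consensus is bundled for this domain, so downstream classification treats
# the RPW8 profile as an optional user input; this synthetic one pairs with
# the synthetic genome generator, which plants exactly this consensus.
SYNTHETIC_RPW8_CONSENSUS = "WxxAIxDAAxxKLxxxlxxEVxxLxxVxxExAxxIQ"


def synthetic_rpw8_profile() -> ConsensusMotif:
    """Synthetic RPW8-like N-terminal profile (not from any publication)."""
    return parse_consensus(
        SYNTHETIC_RPW8_CONSENSUS,
        name="RPW8",
        family_context="shared",
        region="N-terminal",
        source="synthetic",
    )
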