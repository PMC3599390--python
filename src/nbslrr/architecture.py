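"""Domain-architecture classification of NBS-LRR candidate proteins.

Domains (TIR, CC, NBS, LRR, RPW8) are called from consensus-motif hits plus
a heptad-periodicity coiled-coil detector, then mapped onto the seven
architecture letter codes used for this gene family (TNL, CNL, TN, CN, N,
NL, RPW8-NL). The TIR-vs-CC family of a protein is additionally predicted
from the diagnostic terminal residue of its kinase-2 motif (D -> TIR,
W -> CC), and the conserved P-loop..GLPL core is extracted for phylogeny.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .motifs import ConsensusMotif, MotifHit, load_paper_motifs, scan_sequence

LETTER_CODES = ("TNL", "CNL", "TN", "CN", "N", "NL", "RPW8-NL", "unclassified")

#: the eight NBS-domain core motifs; table names map onto these categories
CORE_MOTIF_CATEGORY = {
    "P-loop": "P-loop",
    "RNBS-A-nonTIR": "RNBS-A",
    "RNBS-A-TIR": "RNBS-A",
    "Kinase-2": "Kinase-2",
    "RNBS-B": "RNBS-B",
    "RNBS-C": "RNBS-C",
    "GLPL": "GLPL",
    "RNBS-D-nonTIR": "RNBS-D",
    "RNBS-D-TIR": "RNBS-D",
    "MHDV": "MHD",
    "MHDL": "MHD",
}
N_CORE_CATEGORIES = 8

TIR_MOTIFS = ("T1", "T2", "T3", "T4")
CC_MOTIFS = ("C1", "C2", "C3")
LRR_MOTIFS = ("L1", "L2", "L3", "L4", "L5", "L6", "L7")

HYDROPHOBIC = frozenset("LIVMFYWA")


@dataclass
class DomainArchitecture:
    gene_id: str
    domains: list = field(default_factory=list)  # (name, start, end) N->C order
    letter_code: str = "unclassified"
    kinase2_last_residue: str | None = None
    kinase2_family_call: str = "undetermined"
    nbs_core: str | None = None
    hits: list = field(default_factory=list)

    @property
    def domain_names(self) -> set:
        return {d[0] for d in self.domains}


def detect_coiled_coil(
    protein: str, window: int = 28, threshold: float = 0.8
) -> list[tuple[int, int, float]]:
    """Sliding-window heptad-periodicity score for coiled-coil segments.

    For each window the fraction of hydrophobic residues at heptad positions
    a/d is combined with the depletion of hydrophobics elsewhere
    (``f_ad * (1 - f_other)``), maximised over the 7 possible frame offsets,
    giving a score in [0, 1]. Windows above ``threshold`` are merged into
    segments reported as (start, end, max_score). This is a lightweight
    surrogate for full coiled-coil profile methods; the threshold default was
    calibrated on constructed heptad-repeat positives and shuffled/poly-G
    negatives.
    """
    n = len(protein)
    if n < window:
        return []
    if window % 7 != 0:
        raise ValueError("window must be a multiple of 7")
    hyd = np.array([c in HYDROPHOBIC for c in protein.upper()], dtype=float)
    idx = np.arange(n)
    n_ad = 2 * window // 7
    n_other = window - n_ad
    best = np.zeros(n - window + 1)
    kernel = np.ones(window)
    for offset in range(7):
        ad = np.isin((idx + offset) % 7, (0, 3))
        ad_counts = np.convolve(hyd * ad, kernel, mode="valid")
        other_counts = np.convolve(hyd * (~ad), kernel, mode="valid")
        score = (ad_counts / n_ad) * (1.0 - other_counts / n_other)
        best = np.maximum(best, score)
    segments: list[tuple[int, int, float]] = []
    above = best >= threshold
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            segments.append((i, j + window, float(best[i : j + 1].max())))
            i = j + 1
        i += 1
    return segments


def coiled_coil_score(protein: str, window: int = 28) -> float:
    """Maximum heptad-periodicity window score over the whole protein."""
    n = len(protein)
    if n < window:
        return 0.0
    segs = detect_coiled_coil(protein, window=window, threshold=1e-9)
    return max(s[2] for s in segs) if segs else 0.0


def _best_hit(hits: Sequence[MotifHit], name: str) -> MotifHit | None:
    cands = [h for h in hits if h.motif_name == name]
    if not cands:
        return None
    return max(cands, key=lambda h: (h.normalized_score, -h.start))


def call_domains(
    protein: str,
    motif_hits: Sequence[MotifHit],
    cc_segments: Sequence[tuple] = (),
    rpw8_hits: Sequence[MotifHit] = (),
    gene_id: str = "",
    tir_quorum: int = 2,
    cc_quorum: int = 2,
    nbs_quorum: int = 4,
    lrr_quorum: int = 2,
) -> DomainArchitecture:
    """Call TIR/CC/NBS/LRR/RPW8 domains from motif hits.

    Quorum rules (positions are protein coordinates):

    * NBS: >= ``nbs_quorum`` of the 8 core motif categories hit, including
      the P-loop.
    * TIR: >= ``tir_quorum`` of T1-T4 hit N-terminal of the P-loop.
    * CC: a coiled-coil segment, or >= ``cc_quorum`` of C1-C3, N-terminal of
      the P-loop.
    * LRR: >= ``lrr_quorum`` distinct L-motifs C-terminal of the GLPL.
    * RPW8: a hit of a user-supplied RPW8 profile N-terminal of the P-loop.
    """
    arch = DomainArchitecture(gene_id=gene_id, hits=list(motif_hits))
    ploop = _best_hit(motif_hits, "P-loop")
    glpl = _best_hit(motif_hits, "GLPL")
    anchor = ploop.start if ploop is not None else len(protein)

    core_hits = [h for h in motif_hits if h.motif_name in CORE_MOTIF_CATEGORY]
    core_categories = {CORE_MOTIF_CATEGORY[h.motif_name] for h in core_hits}
    domains: list[tuple[str, int, int]] = []

    rpw8_before = [h for h in rpw8_hits if h.end <= anchor]
    if rpw8_before:
        domains.append(
            ("RPW8", min(h.start for h in rpw8_before), max(h.end for h in rpw8_before))
        )

    t_hits = [h for h in motif_hits if h.motif_name in TIR_MOTIFS and h.end <= anchor]
    if len({h.motif_name for h in t_hits}) >= tir_quorum:
        domains.append(("TIR", min(h.start for h in t_hits), max(h.end for h in t_hits)))

    c_hits = [h for h in motif_hits if h.motif_name in CC_MOTIFS and h.end <= anchor]
    cc_before = [s for s in cc_segments if s[0] < anchor]
    if len({h.motif_name for h in c_hits}) >= cc_quorum or cc_before:
        spans = [(h.start, h.end) for h in c_hits] + [(s[0], s[1]) for s in cc_before]
        domains.append(("CC", min(s for s, _ in spans), max(e for _, e in spans)))

    if ploop is not None and len(core_categories) >= nbs_quorum:
        domains.append(
            ("NBS", min(h.start for h in core_hits), max(h.end for h in core_hits))
        )

    if glpl is not None:
        l_hits = [
            h for h in motif_hits if h.motif_name in LRR_MOTIFS and h.start >= glpl.end
        ]
        if len({h.motif_name for h in l_hits}) >= lrr_quorum:
            domains.append(
                ("LRR", min(h.start for h in l_hits), max(h.end for h in l_hits))
            )

    arch.domains = sorted(domains, key=lambda d: d[1])
    return arch


def letter_code(architecture: DomainArchitecture) -> str:
    """Deterministic, total mapping from domain calls to the letter code.

    RPW8 outranks CC (RPW8-NL is its own category); TIR outranks CC when
    both fire; no NBS means unclassified.
    """
    names = architecture.domain_names
    if "NBS" not in names:
        return "unclassified"
    lrr = "LRR" in names
    if "RPW8" in names and lrr:
        return "RPW8-NL"
    if "TIR" in names:
        return "TNL" if lrr else "TN"
    if "CC" in names:
        return "CNL" if lrr else "CN"
    return "NL" if lrr else "N"


def kinase2_diagnostic_index(motif: ConsensusMotif) -> int:
    """Index of the family-diagnostic residue in a kinase-2 consensus: the
    position immediately following the conserved D-D-V run (falls back to
    the final position when no such run exists)."""
    for i in range(motif.length - 3):
        window = motif.positions[i : i + 3]
        if all(
            p.residues == frozenset(a) for p, a in zip(window, ("D", "D", "V"))
        ) and i + 3 < motif.length:
            return i + 3
    return motif.length - 1


def predict_family_kinase2(
    protein: str,
    motif_hits: Sequence[MotifHit],
    motif_library: Sequence[ConsensusMotif] | None = None,
) -> tuple[str, str | None]:
    """Predict the TIR/CC family from the kinase-2 terminal residue.

    Returns ``(call, residue)`` where call is ``"TIR"`` (residue D),
    ``"CC"`` (residue W) or ``"undetermined"`` (any other residue, or no
    kinase-2 hit at all, in which case residue is None).
    """
    if motif_library is None:
        motif_library = load_paper_motifs()
    k2_hits = [h for h in motif_hits if h.motif_name == "Kinase-2"]
    if not k2_hits:
        return "undetermined", None
    hit = max(k2_hits, key=lambda h: (h.normalized_score, -h.start))
    motif = next(
        m
        for m in motif_library
        if m.name == "Kinase-2" and m.family_context == hit.family_context
    )
    residue = protein[hit.start + kinase2_diagnostic_index(motif)]
    if residue == "D":
        return "TIR", residue
    if residue == "W":
        return "CC", residue
    return "undetermined", residue


def extract_nbs_core(
    protein: str, motif_hits: Sequence[MotifHit]
) -> str | None:
    """P-loop..GLPL subsequence, or None when either anchor motif is missing
    or mis-ordered (such proteins are excluded from phylogeny)."""
    ploop = _best_hit(motif_hits, "P-loop")
    glpl = _best_hit(motif_hits, "GLPL")
    if ploop is None or glpl is None or ploop.start >= glpl.start:
        return None
    return protein[ploop.start : glpl.end]


def classify_protein(
    gene_id: str,
    protein: str,
    motif_library: Sequence[ConsensusMotif] | None = None,
    threshold: float = 0.6,
    rpw8_profile: ConsensusMotif | None = None,
    cc_window: int = 28,
    cc_threshold: float = 0.8,
    **quorums,
) -> DomainArchitecture:
    """Full per-protein classification: scan, call domains, assign the letter
    code, predict the kinase-2 family, and extract the P-loop..GLPL core."""
    if motif_library is None:
        motif_library = load_paper_motifs()
    hits = scan_sequence(protein, motif_library, threshold=threshold)
    cc_segments = detect_coiled_coil(protein, window=cc_window, threshold=cc_threshold)
    rpw8_hits = (
        scan_sequence(protein, [rpw8_profile], threshold=threshold)
        if rpw8_profile is not None
        else []
    )
    arch = call_domains(
        protein, hits, cc_segments=cc_segments, rpw8_hits=rpw8_hits, gene_id=gene_id,
        **quorums,
    )
    arch.letter_code = letter_code(arch)
    arch.kinase2_family_call, arch.kinase2_last_residue = predict_family_kinase2(
        protein, hits, motif_library
    )
    arch.nbs_core = extract_nbs_core(protein, hits)
    return arch


def summarize_categories(architectures: Iterable[DomainArchitecture]) -> dict:
    """Counts per letter code plus a ``total`` entry equal to the input size."""
    archs = list(architectures)
    if not archs:
        raise ValueError("empty architecture list")
    counts = Counter(a.letter_code for a in archs)
    out = dict(counts)
    out["total"] = len(archs)
    return out


class FrameError(ValueError):
    pass


STOP_CODONS = {"TAA", "TAG", "TGA"}


def screen_pseudogenes(cds_or_orf: str) -> str:
    """Classify an in-frame nucleotide sequence: ``"pseudogene"`` iff an
    internal stop codon occurs before the final codon, else ``"clean"``."""
    seq = cds_or_orf.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for codon in codons[:-1]:
        if codon in STOP_CODONS:
            return "pseudogene"
    return "clean"
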