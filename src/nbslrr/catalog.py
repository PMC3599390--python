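"""Accession catalog of NBS-encoding genes and RGHs in cucurbit crops.

The bundled fixture transcribes the published accession table literally,
including its "Cacsa." gene-id spelling (the running text uses "Cucsa.";
the two are treated as one namespace) and the apparently truncated id
"Cacsa.37190". Flags follow the printed convention: ``*`` marks a
pseudogene, ``#`` marks a sequence lacking the complete P-loop..GLPL core.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

_FIXTURE = "catalog_table1.tsv"

_RANGE = re.compile(r"^([A-Za-z_.]+?)(\d+)\s*-\s*([A-Za-z_.]+?)(\d+)$")
_FLAGS = ("*", "#")


@dataclass(frozen=True)
class CatalogEntry:
    species: str
    scientific_name: str
    family: str  # "TIR-NBS" | "CC-NBS"
    accession: str
    source: str  # "database" | "this-study" | "reference"
    source_detail: str
    pseudogene: bool
    incomplete_core: bool


class AccessionRangeError(ValueError):
    pass


def _split_flags(token: str) -> tuple[str, str]:
    flags = ""
    while token and token[-1] in _FLAGS:
        flags += token[-1]
        token = token[:-1]
    return token.strip(), flags


def expand_accession_ranges(entry_text: str) -> list[tuple[str, str]]:
    """Expand comma-separated accession tokens; hyphenated ranges are
    inclusive. Returns ``(accession, flags)`` pairs in written order.

    Range endpoints must share their alphabetic prefix and digit width and
    satisfy start <= end.
    """
    out: list[tuple[str, str]] = []
    for raw in entry_text.split(","):
        token = raw.strip()
        if not token:
            continue
        token, flags = _split_flags(token)
        m = _RANGE.match(token)
        if m:
            p1, d1, p2, d2 = m.groups()
            if p1 != p2:
                raise AccessionRangeError(f"prefix mismatch in range {token!r}")
            if len(d1) != len(d2):
                raise AccessionRangeError(f"digit width mismatch in range {token!r}")
            if int(d1) > int(d2):
                raise AccessionRangeError(f"start > end in range {token!r}")
            for v in range(int(d1), int(d2) + 1):
                out.append((f"{p1}{v:0{len(d1)}d}", flags))
        else:
            out.append((token, flags))
    return out


def load_catalog() -> pd.DataFrame:
    """Expanded per-accession catalog as a DataFrame."""
    entries: list[CatalogEntry] = []
    path = resources.files("nbslrr.data").joinpath(_FIXTURE)
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            for accession, flags in expand_accession_ranges(row["accessions"]):
                entries.append(
                    CatalogEntry(
                        species=row["species"],
                        scientific_name=row["scientific_name"],
                        family=row["family"],
                        accession=accession,
                        source=row["source"],
                        source_detail=row["source_detail"],
                        pseudogene="*" in flags,
                        incomplete_core="#" in flags,
                    )
                )
    return pd.DataFrame(entries)


def count_catalog(catalog: pd.DataFrame, group_by) -> pd.Series:
    """Entry counts grouped by one or more columns; totals are conserved."""
    if catalog.empty:
        return pd.Series(dtype=int)
    return catalog.groupby(group_by, sort=True).size()


def apply_exclusions(catalog: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove pseudogenes (``*``) and incomplete-core (``#``) entries.

    Returns ``(retained, removed)``; their union is the input.
    """
    mask = catalog["pseudogene"] | catalog["incomplete_core"]
    return catalog[~mask].reset_index(drop=True), catalog[mask].reset_index(drop=True)


def normalize_gene_id(gene_id: str) -> str:
    """Map the table's "Cacsa." spelling onto the text's "Cucsa." namespace."""
    return gene_id.replace("Cacsa.", "Cucsa.")


def audit(catalog: pd.DataFrame | None = None) -> dict:
    """Key counts plus internal-consistency checks of the catalog.

    Notably, the text claims 103 PCR-derived sequences spanning
    JN230598-JN230701, but that accession span holds 104 ids; the audit
    reports both rather than resolving the discrepancy.
    """
    if catalog is None:
        catalog = load_catalog()
    cucumber = catalog[catalog["species"] == "Cucumber"]
    others = catalog[catalog["species"] != "Cucumber"]
    jn = catalog[catalog["accession"].str.startswith("JN230")]
    per_species = count_catalog(others, "species").to_dict()
    retained, removed = apply_exclusions(catalog)
    return {
        "cucumber_total": int(len(cucumber)),
        "cucumber_tir": int((cucumber["family"] == "TIR-NBS").sum()),
        "cucumber_cc": int((cucumber["family"] == "CC-NBS").sum()),
        "non_cucumber_total": int(len(others)),
        "per_species": per_species,
        "melon_pcr": int(
            ((others["species"] == "Melon") & (others["source"] == "this-study")).sum()
        ),
        "pcr_accessions_in_span": int(len(jn)),
        "pcr_accessions_claimed": 103,
        "pcr_span_discrepancy": int(len(jn)) != 103,
        "excluded_flagged": int(len(removed)),
        "retained": int(len(retained)),
    }
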