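"""Build a cancer-associated variant dataset from a GWAS-catalog-style
association table and select the nonsynonymous SNPs.

The catalog is filtered on trait keywords (default: cancer, carcinoma,
glioma, leukemia, lymphoma, melanoma, sarcoma; case-insensitive
substring match), deduplicated on (rsid, trait), and censused by
consequence class.  Only nsSNPs go forward to prediction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .types import (
    AminoAcidChange,
    ConsequenceClass,
    GwasAssociation,
    parse_consequence,
)

__all__ = [
    "CANCER_KEYWORDS",
    "CatalogFilterSpec",
    "filter_catalog",
    "consequence_census",
    "select_nssnps",
    "read_catalog",
    "write_census_json",
]

CANCER_KEYWORDS = (
    "cancer",
    "carcinoma",
    "glioma",
    "leukemia",
    "lymphoma",
    "melanoma",
    "sarcoma",
)


@dataclass(frozen=True)
class CatalogFilterSpec:
    """Trait-keyword filter.

    ``word_boundary=False`` (default) matches substrings, so e.g.
    'sarcoma' also catches 'leiomyosarcoma' — compound tumour names are
    intended matches.  Word-boundary matching is available for stricter
    dialects.
    """

    keywords: tuple = CANCER_KEYWORDS
    word_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword list must be non-empty")
        object.__setattr__(
            self, "keywords", tuple(k.lower() for k in self.keywords)
        )

    def matches(self, trait: str) -> bool:
        text = trait.lower()
        if self.word_boundary:
            return any(
                re.search(rf"\b{re.escape(k)}\b", text) for k in self.keywords
            )
        return any(k in text for k in self.keywords)


def filter_catalog(
    rows: Sequence[GwasAssociation],
    spec: CatalogFilterSpec = CatalogFilterSpec(),
) -> list[GwasAssociation]:
    """Keep rows whose trait mentions at least one keyword.

    Deduplicates on (rsid, trait) keeping the first occurrence; the
    same variant under two distinct traits is retained twice (it is two
    associations).  Order is stable, and the filter is idempotent.
    """
    seen: set = set()
    out: list[GwasAssociation] = []
    for row in rows:
        if not spec.matches(row.trait):
            continue
        key = (row.rsid, row.trait)
        if key in seen:
            continue
        seen.add(key)
        out.append(row)
    return out


def consequence_census(
    rows: Sequence[GwasAssociation],
) -> dict[ConsequenceClass, int]:
    """Count rows per consequence class; counts partition the input."""
    census: dict[ConsequenceClass, int] = {}
    for row in rows:
        census[row.consequence] = census.get(row.consequence, 0) + 1
    return census


def select_nssnps(rows: Sequence[GwasAssociation]) -> list[GwasAssociation]:
    """The nonsynonymous subset, order preserved."""
    return [r for r in rows if r.consequence is ConsequenceClass.NONSYNONYMOUS]


DEFAULT_COLUMN_MAP = {
    "rsid": "rsid",
    "chrom": "chrom",
    "pos": "pos",
    "trait": "trait",
    "gene": "gene",
    "consequence": "consequence",
    "risk_allele": "risk_allele",
    "risk_allele_freq": "risk_allele_freq",
    "protein_accession": "protein_accession",
    "aa_change": "aa_change",
}


def read_catalog(
    path,
    column_map: Optional[dict] = None,
) -> list[GwasAssociation]:
    """Read an association table (TSV with header).

    ``column_map`` maps our field names to the file's column names —
    catalog dialects drift (e.g. ``{"trait": "DISEASE/TRAIT"}`` or
    ``{"trait": "MAPPED_TRAIT"}``).  Unmapped optional columns are
    simply absent.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")

    for required in ("rsid", "chrom", "pos", "trait", "gene", "consequence"):
        if cmap[required] not in df.columns:
            raise ValueError(
                f"catalog missing required column {cmap[required]!r}"
            )

    def get(row, name):
        col = cmap.get(name)
        if col is None or col not in df.columns:
            return None
        cell = str(row[col]).strip()
        return cell or None

    rows: list[GwasAssociation] = []
    for i, row in df.iterrows():
        try:
            consequence = parse_consequence(str(row[cmap["consequence"]]))
        except ValueError as exc:
            raise ValueError(f"catalog row {i}: {exc}") from None
        aa_cell = get(row, "aa_change")
        freq_cell = get(row, "risk_allele_freq")
        rows.append(
            GwasAssociation(
                rsid=str(row[cmap["rsid"]]).strip(),
                chrom=str(row[cmap["chrom"]]).strip(),
                pos=int(str(row[cmap["pos"]]).replace(",", "")),
                trait=str(row[cmap["trait"]]).strip(),
                gene=str(row[cmap["gene"]]).strip(),
                consequence=consequence,
                risk_allele=get(row, "risk_allele"),
                risk_allele_freq=None if freq_cell is None else float(freq_cell),
                protein_accession=get(row, "protein_accession"),
                aa_change=None if aa_cell is None else AminoAcidChange.parse(aa_cell),
            )
        )
    return rows


def write_census_json(census: dict[ConsequenceClass, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {k.value: v for k, v in sorted(census.items(), key=lambda kv: kv[0].value)},
            fh,
            indent=2,
        )
        fh.write("\n")
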