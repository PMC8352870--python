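"""Match dataset variants against cohort VCFs under quality filters.

A dataset variant is "found" in a cohort when a VCF record at the same
chrom+pos passes the quality filter (site depth >= 5 and Phred quality
>= 30 by default; the bounds are inclusive — only strictly-below values
are excluded) and the alternate allele is observed in at least one
sample.  Matching by rsID in the VCF ID column is the fallback when the
dataset row carries no coordinates.

Allele frequency is the alternate-allele count over non-missing called
alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from cyvcf2 import VCF

from .types import GwasAssociation

__all__ = [
    "QualityFilterSpec",
    "CohortVariant",
    "passes_quality",
    "allele_frequency",
    "match_dataset",
]


@dataclass(frozen=True)
class QualityFilterSpec:
    """Site-level quality filter: minimum read depth and Phred quality.

    ``on_absent`` decides what to do when a record lacks DP or QUAL:
    "fail" (default, fail closed) or "pass".
    """

    min_depth: int = 5
    min_qual: float = 30.0
    on_absent: str = "fail"


@dataclass
class CohortVariant:
    """One cohort site: coordinates, alleles, genotypes and quality."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    genotypes: tuple  # GT strings, e.g. ("0/1", "./.")
    depth: Optional[int]
    qual: Optional[float]
    rsid: Optional[str] = None

    @property
    def allele_freq(self) -> Optional[float]:
        return allele_frequency(self.genotypes)


def passes_quality(v: CohortVariant, spec: QualityFilterSpec = QualityFilterSpec()) -> bool:
    """Depth >= min_depth AND qual >= min_qual (both inclusive)."""
    if v.depth is None or v.qual is None:
        if spec.on_absent == "pass":
            return True
        if spec.on_absent == "fail":
            return False
        raise ValueError(f"unknown on_absent policy {spec.on_absent!r}")
    return v.depth >= spec.min_depth and v.qual >= spec.min_qual


def allele_frequency(genotypes: Iterable[str]) -> Optional[float]:
    """Alt-allele fraction over non-missing called alleles.

    Missing alleles ('.') leave the denominator.  Returns None when
    every allele is missing.  Raises on malformed GT strings, naming
    the offending sample index.
    """
    alt = called = 0
    for i, gt in enumerate(genotypes):
        alleles = gt.replace("|", "/").split("/")
        if len(alleles) != 2:
            raise ValueError(f"sample {i}: malformed genotype {gt!r}")
        for a in alleles:
            if a == ".":
                continue
            if not a.isdigit():
                raise ValueError(f"sample {i}: malformed genotype {gt!r}")
            called += 1
            if int(a) > 0:
                alt += 1
    if called == 0:
        return None
    return alt / called


def _normalize_contig(name: str, aliases: Optional[dict]) -> str:
    if aliases and name in aliases:
        return aliases[name]
    return name[3:] if name.lower().startswith("chr") else name


def _site_depth(variant) -> Optional[int]:
    """INFO/DP when present, else the sum of per-sample FORMAT/DP."""
    dp = variant.INFO.get("DP")
    if dp is not None:
        return int(dp)
    try:
        fmt_dp = variant.format("DP")
    except KeyError:
        return None
    if fmt_dp is None:
        return None
    total = int(fmt_dp[fmt_dp >= 0].sum())
    return total if (fmt_dp >= 0).any() else None


def iter_cohort_variants(vcf_path) -> Iterable[CohortVariant]:
    """Stream a VCF as CohortVariants, splitting multi-allelic records
    into one CohortVariant per alternate allele (genotypes are recoded
    so the focal alt is allele 1 and every other alt is 0)."""
    vcf = VCF(str(vcf_path))
    for variant in vcf:
        depth = _site_depth(variant)
        qual = variant.QUAL
        for alt_index, alt in enumerate(variant.ALT, start=1):
            recoded = []
            for g in variant.genotypes:  # [a0, a1, phased]
                sep = "|" if g[2] else "/"
                coded = [
                    "." if a < 0 else ("1" if a == alt_index else "0")
                    for a in (g[0], g[1])
                ]
                recoded.append(sep.join(coded))
            recoded = tuple(recoded)
            yield CohortVariant(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=alt,
                genotypes=recoded,
                depth=depth,
                qual=None if qual is None else float(qual),
                rsid=variant.ID,
            )


def _alt_observed(v: CohortVariant) -> bool:
    return any(
        a == "1"
        for gt in v.genotypes
        for a in gt.replace("|", "/").split("/")
    )


def match_dataset(
    vcf_paths: Sequence,
    dataset: Sequence[GwasAssociation],
    spec: QualityFilterSpec = QualityFilterSpec(),
    contig_aliases: Optional[dict] = None,
) -> dict[str, CohortVariant]:
    """Which dataset variants are present in the cohort?

    Returns rsid -> the passing CohortVariant that matched it (first
    match wins across files).  A site matches on chrom+pos with the
    alternate allele observed in >= 1 sample; when the dataset row
    carries a risk allele, only that alternate counts.  Contig names
    are normalized by stripping a 'chr' prefix plus any explicit
    aliases.
    """
    by_coord: dict[tuple, list[GwasAssociation]] = {}
    by_rsid: dict[str, GwasAssociation] = {}
    for row in dataset:
        by_coord.setdefault(
            (_normalize_contig(row.chrom, contig_aliases), row.pos), []
        ).append(row)
        by_rsid[row.rsid] = row

    matched: dict[str, CohortVariant] = {}
    for path in vcf_paths:
        for v in iter_cohort_variants(path):
            if not passes_quality(v, spec):
                continue
            if not _alt_observed(v):
                continue
            key = (_normalize_contig(v.chrom, contig_aliases), v.pos)
            candidates = by_coord.get(key, [])
            if not candidates and v.rsid in by_rsid:
                candidates = [by_rsid[v.rsid]]
            for row in candidates:
                if row.risk_allele is not None and row.risk_allele != v.alt:
                    continue
                matched.setdefault(row.rsid, v)
    return matched
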