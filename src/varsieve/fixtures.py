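"""Packaged reference tables for the candidate-variant pipeline.

Machine-readable transcriptions of the published printed tables: the
model-benchmark confusion counts, the 48 recoverable cohort candidate
variants with per-tool labels, and conservation / stability / structure
/ annotation evidence for the eight high-risk variants.  Everything is
validated against the core type invariants at load, and file checksums
are verified against a manifest.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass

import pandas as pd

from .thresholds import DEFAULT_THRESHOLDS, ThresholdConfig, classify
from .types import (
    AminoAcidChange,
    ConfusionCounts,
    ConservationCall,
    ModPredCall,
    MutPredCall,
    PredictionProfile,
    StabilityCall,
    StabilityDirection,
    StructureCall,
    Tool,
    validate_profile,
)

__all__ = [
    "HIGH_RISK_RSIDS",
    "SHORTLIST_RSIDS",
    "FixtureBundle",
    "fixtures",
    "confusion_counts",
    "variant_table",
    "variant_profiles",
    "candidate_profiles",
]

#: The eight variants called deleterious by the published >=4-of-5 rule.
HIGH_RISK_RSIDS = (
    "rs3124765",
    "rs9379084",
    "rs10936600",
    "rs1801591",
    "rs117744081",
    "rs2277283",
    "rs757978",
    "rs1126809",
)

#: The final shortlist after the stability and structure gates.
SHORTLIST_RSIDS = ("rs10936600", "rs757978", "rs1126809")

_DATA = importlib.resources.files("varsieve") / "data"


class FixtureChecksumError(RuntimeError):
    """Packaged data no longer matches its manifest."""


def _read(name: str, verify: bool = True) -> str:
    text = (_DATA / name).read_text()
    if verify:
        manifest = json.loads((_DATA / "manifest.json").read_text())
        digest = hashlib.sha256(text.encode()).hexdigest()
        if manifest.get(name) != digest:
            raise FixtureChecksumError(
                f"{name}: checksum {digest} does not match manifest"
            )
    return text


def _read_tsv(name: str) -> pd.DataFrame:
    import io

    return pd.read_csv(
        io.StringIO(_read(name)),
        sep="\t",
        dtype=str,
        keep_default_na=False,
        comment="#",
    )


def confusion_counts() -> dict[str, ConfusionCounts]:
    """Per-model benchmark confusion counts (8 models, n = 50/50)."""
    df = _read_tsv("model_benchmark_confusion.tsv")
    return {
        row["model"]: ConfusionCounts(
            tp=int(row["tp"]), fn=int(row["fn"]), tn=int(row["tn"]), fp=int(row["fp"])
        )
        for _, row in df.iterrows()
    }


def variant_table() -> pd.DataFrame:
    """The cohort candidate variants with per-tool labels (48 rows)."""
    return _read_tsv("cohort_candidate_variants.tsv")


_LABEL_COLUMNS = {
    Tool.SIFT: "sift_label",
    Tool.POLYPHEN2: "pp2_label",
    Tool.CONDEL: "condel_label",
    Tool.PROVEAN: "provean_label",
    Tool.PANTHER: "panther_label",
}


def variant_profiles(
    cfg: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> list[PredictionProfile]:
    """Candidate variants as PredictionProfiles (labels resolved to
    calls; no conservation/stability evidence attached)."""
    profiles = []
    for _, row in variant_table().iterrows():
        calls = []
        for tool, col in _LABEL_COLUMNS.items():
            label = row[col].strip() or None
            calls.append(classify(tool, score=None, label=label, cfg=cfg))
        profile = PredictionProfile(
            rsid=row["rsid"],
            gene=row["gene"],
            aa_change=AminoAcidChange.parse(row["aa_change"]),
            functional_calls=tuple(calls),
            trait=row["trait"],
        )
        violations = validate_profile(profile)
        if violations:
            raise ValueError(f"{profile.rsid}: invalid fixture row: {violations}")
        profiles.append(profile)
    return profiles


def conservation_calls() -> dict[str, ConservationCall]:
    df = _read_tsv("high_risk_conservation.tsv")
    return {
        row["rsid"]: ConservationCall(int(row["consurf_score"]))
        for _, row in df.iterrows()
    }


def stability_structure_calls() -> dict[str, tuple]:
    df = _read_tsv("high_risk_stability_structure.tsv")
    out = {}
    for _, row in df.iterrows():
        out[row["rsid"]] = (
            StabilityCall(
                direction=StabilityDirection(row["direction"]),
                ddg=float(row["ddg"]),
                ri=int(row["ri"]),
            ),
            StructureCall(tm_score=float(row["tm_score"]), rmsd=float(row["rmsd"])),
        )
    return out


def annotation_calls() -> dict[str, tuple]:
    df = _read_tsv("shortlist_annotations.tsv")
    out = {}
    for _, row in df.iterrows():
        features = tuple(
            (mech, float(p))
            for mech, p in (
                item.rsplit(":", 1) for item in row["mutpred_features"].split("|")
            )
        )
        out[row["rsid"]] = (
            MutPredCall(score=float(row["mutpred_score"]), features=features),
            ModPredCall(
                ptm_type=row["modpred_ptm"], score=float(row["modpred_score"])
            ),
        )
    return out


def candidate_profiles(
    cfg: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> list[PredictionProfile]:
    """The eight high-risk variants with all available evidence merged
    (tool labels + conservation + stability + structure + annotations),
    ordered as in the conservation table."""
    by_rsid = {p.rsid: p for p in variant_profiles(cfg)}
    conservation = conservation_calls()
    stab_struct = stability_structure_calls()
    annotations = annotation_calls()
    out = []
    for rsid in HIGH_RISK_RSIDS:
        profile = by_rsid[rsid]
        stability, structure = stab_struct[rsid]
        mutpred = modpred = None
        if rsid in annotations:
            mutpred, modpred = annotations[rsid]
        out.append(
            profile.with_evidence(
                conservation=conservation[rsid],
                stability=stability,
                structure=structure,
                mutpred=mutpred,
                modpred=modpred,
            )
        )
    return out


@dataclass(frozen=True)
class FixtureBundle:
    """All packaged tables, parsed and validated."""

    confusion_counts: dict
    variants: pd.DataFrame
    conservation: dict
    stability_structure: dict
    annotations: dict


def fixtures() -> FixtureBundle:
    """Load and validate every packaged table."""
    bundle = FixtureBundle(
        confusion_counts=confusion_counts(),
        variants=variant_table(),
        conservation=conservation_calls(),
        stability_structure=stability_structure_calls(),
        annotations=annotation_calls(),
    )
    variant_profiles()  # validates every row against the type invariants
    return bundle
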