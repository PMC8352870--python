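"""Profile TSV dialect: the flat on-disk form of a PredictionProfile.

One row per variant; an empty cell means "missing".  Columns::

    rsid  gene  aa_change
    sift_score  sift_label  pp2_score  pp2_label  condel_score  condel_label
    provean_score  provean_label  panther_score  panther_label
    consurf_score  imutant_direction  imutant_ddg  imutant_ri
    tm_score  rmsd  mutpred_score  modpred_score

Any valid profile round-trips through this dialect field-for-field
(annotation feature lists and ModPred PTM type excepted: the dialect
stores scores only, as scores are what the pipeline consumes).
"""

from __future__ import annotations

import math
from typing import Optional

import pandas as pd

from .types import (
    AminoAcidChange,
    ConservationCall,
    ModPredCall,
    MutPredCall,
    PredictionProfile,
    StabilityCall,
    StabilityDirection,
    StructureCall,
    Tool,
)

PROFILE_COLUMNS = [
    "rsid",
    "gene",
    "aa_change",
    "sift_score",
    "sift_label",
    "pp2_score",
    "pp2_label",
    "condel_score",
    "condel_label",
    "provean_score",
    "provean_label",
    "panther_score",
    "panther_label",
    "consurf_score",
    "imutant_direction",
    "imutant_ddg",
    "imutant_ri",
    "tm_score",
    "rmsd",
    "mutpred_score",
    "modpred_score",
]

TOOL_PREFIX = {
    Tool.SIFT: "sift",
    Tool.POLYPHEN2: "pp2",
    Tool.CONDEL: "condel",
    Tool.PROVEAN: "provean",
    Tool.PANTHER: "panther",
}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def profile_to_row(profile: PredictionProfile) -> dict:
    """Flatten a profile into one dialect row (dict of strings)."""
    row = {c: "" for c in PROFILE_COLUMNS}
    row["rsid"] = profile.rsid
    row["gene"] = profile.gene
    row["aa_change"] = "" if profile.aa_change is None else str(profile.aa_change)
    for call in profile.functional_calls:
        prefix = TOOL_PREFIX[call.tool]
        row[f"{prefix}_score"] = _cell(call.score)
        row[f"{prefix}_label"] = _cell(call.label)
    if profile.conservation is not None:
        row["consurf_score"] = str(profile.conservation.score)
    if profile.stability is not None:
        row["imutant_direction"] = profile.stability.direction.value
        row["imutant_ddg"] = _cell(profile.stability.ddg)
        row["imutant_ri"] = str(profile.stability.ri)
    if profile.structure is not None:
        row["tm_score"] = _cell(profile.structure.tm_score)
        row["rmsd"] = _cell(profile.structure.rmsd)
    if profile.mutpred is not None:
        row["mutpred_score"] = _cell(profile.mutpred.score)
    if profile.modpred is not None:
        row["modpred_score"] = _cell(profile.modpred.score)
    return row


def _opt_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", "-", "—", "NA", "nan"):
        return None
    return float(cell)


def _opt_str(cell: str) -> Optional[str]:
    cell = cell.strip()
    return None if cell in ("", "-", "—", "NA") else cell


def row_to_profile(row: dict, classify) -> PredictionProfile:
    """Rebuild a profile from one dialect row.

    ``classify`` is the per-tool resolver, ``classify(tool, score,
    label) -> ToolCall`` (see :mod:`varsieve.thresholds`); the dialect
    stores raw evidence, not resolved calls.
    """
    calls = []
    for tool, prefix in TOOL_PREFIX.items():
        score = _opt_float(str(row.get(f"{prefix}_score", "")))
        label = _opt_str(str(row.get(f"{prefix}_label", "")))
        calls.append(classify(tool, score=score, label=label))

    aa_cell = _opt_str(str(row.get("aa_change", "")))
    aa_change = None if aa_cell is None else AminoAcidChange.parse(aa_cell)

    consurf = _opt_float(str(row.get("consurf_score", "")))
    conservation = None if consurf is None else ConservationCall(int(consurf))

    direction = _opt_str(str(row.get("imutant_direction", "")))
    ddg = _opt_float(str(row.get("imutant_ddg", "")))
    ri = _opt_float(str(row.get("imutant_ri", "")))
    stability = None
    if direction is not None or ddg is not None or ri is not None:
        if direction is None or ddg is None or ri is None:
            raise ValueError(
                f"{row.get('rsid')}: stability needs direction, ddg and ri"
            )
        stability = StabilityCall(
            StabilityDirection(direction.lower()), ddg, int(ri)
        )

    tm = _opt_float(str(row.get("tm_score", "")))
    rmsd = _opt_float(str(row.get("rmsd", "")))
    structure = None
    if tm is not None or rmsd is not None:
        if tm is None or rmsd is None:
            raise ValueError(
                f"{row.get('rsid')}: structure needs both tm_score and rmsd"
            )
        structure = StructureCall(tm, rmsd)

    mutpred_score = _opt_float(str(row.get("mutpred_score", "")))
    mutpred = None if mutpred_score is None else MutPredCall(mutpred_score)
    modpred_score = _opt_float(str(row.get("modpred_score", "")))
    modpred = (
        None if modpred_score is None else ModPredCall("unspecified", modpred_score)
    )

    return PredictionProfile(
        rsid=str(row["rsid"]).strip(),
        gene=str(row.get("gene", "")).strip(),
        aa_change=aa_change,
        functional_calls=tuple(calls),
        conservation=conservation,
        stability=stability,
        structure=structure,
        mutpred=mutpred,
        modpred=modpred,
    )


def write_profiles(profiles, path) -> None:
    """Write profiles to a dialect TSV."""
    df = pd.DataFrame([profile_to_row(p) for p in profiles], columns=PROFILE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_profile_table(path) -> pd.DataFrame:
    """Read a dialect TSV as strings (no type coercion surprises)."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing = [c for c in ("rsid",) if c not in df.columns]
    if missing:
        raise ValueError(f"profile TSV missing mandatory columns: {missing}")
    return df
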