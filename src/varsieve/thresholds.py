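"""Per-tool significance thresholds and call resolution.

Each external predictor reports a score and/or a categorical label; this
module resolves either into a significant / not_significant / missing
call using the damaging-direction thresholds:

======== ======================= ==========================
tool     significant (score)     significant (label)
======== ======================= ==========================
SIFT     score <= 0.05           Del, Del_low_con
PolyPhen score > 0.9             Prob_dam (pos_dam is NOT)
Condel   score > 0.5             Del
PROVEAN  score <= -2.5           Del
PANTHER  PSEP > 450 My           Prob_dam (Pos_dam is NOT)
======== ======================= ==========================

When both a score and a label are present and disagree, the score wins
by default (labels are quantized scores; the number carries more
information).  Labels suffixed ``_low_con`` carry the base label's call
with a low-confidence flag preserved as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dialect import read_profile_table, row_to_profile
from .types import CallState, PredictionProfile, Tool, ToolCall

__all__ = ["ThresholdConfig", "DEFAULT_THRESHOLDS", "classify", "load_profiles"]


def _default_label_maps() -> dict:
    sig, not_sig = CallState.SIGNIFICANT, CallState.NOT_SIGNIFICANT
    return {
        Tool.SIFT: {
            "del": (sig, False),
            "del_low_con": (sig, True),
            "tol": (not_sig, False),
            "tol_low_con": (not_sig, True),
        },
        Tool.POLYPHEN2: {
            "benign": (not_sig, False),
            "pos_dam": (not_sig, False),
            "prob_dam": (sig, False),
        },
        Tool.CONDEL: {
            "del": (sig, False),
            "neu": (not_sig, False),
        },
        Tool.PROVEAN: {
            "del": (sig, False),
            "neu": (not_sig, False),
        },
        Tool.PANTHER: {
            "prob_ben": (not_sig, False),
            "pos_dam": (not_sig, False),
            "prob_dam": (sig, False),
        },
    }


@dataclass
class ThresholdConfig:
    """Significance thresholds and label maps for the five predictors.

    Parameters
    ----------
    sift_max : float
        SIFT significance bound; with ``sift_inclusive`` (default) a
        score equal to the bound is significant.
    pp2_min : float
        PolyPhen-2 bound, exclusive (score must exceed it).
    condel_min : float
        Condel bound, exclusive.  Setting it to 1.0 reproduces the
        stricter exact-consensus reading; the default 0.5 is the usable
        rule for a continuous score.
    provean_max : float
        PROVEAN bound, inclusive in the damaging (negative) direction.
    panther_min : float
        PANTHER position-specific evolutionary preservation bound in
        millions of years, exclusive.
    prefer : {"score", "label"}
        Which evidence wins when both are present and disagree.
    """

    sift_max: float = 0.05
    sift_inclusive: bool = True
    pp2_min: float = 0.9
    condel_min: float = 0.5
    provean_max: float = -2.5
    panther_min: float = 450.0
    prefer: str = "score"
    label_maps: dict = field(default_factory=_default_label_maps)

    def score_significant(self, tool: Tool, score: float) -> bool:
        if tool is Tool.SIFT:
            return score <= self.sift_max if self.sift_inclusive else score < self.sift_max
        if tool is Tool.POLYPHEN2:
            return score > self.pp2_min
        if tool is Tool.CONDEL:
            return score > self.condel_min
        if tool is Tool.PROVEAN:
            return score <= self.provean_max
        if tool is Tool.PANTHER:
            return score > self.panther_min
        raise ValueError(f"unknown tool {tool!r}")

    def label_call(self, tool: Tool, label: str) -> tuple:
        table = self.label_maps[tool]
        key = label.strip().lower()
        try:
            return table[key]
        except KeyError:
            raise ValueError(
                f"unknown {tool.value} label {label!r}; known labels: "
                + ", ".join(sorted(table))
            ) from None


DEFAULT_THRESHOLDS = ThresholdConfig()


def classify(
    tool: Tool,
    score: Optional[float] = None,
    label: Optional[str] = None,
    cfg: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> ToolCall:
    """Resolve one predictor output into a ToolCall.

    With neither score nor label the call is ``missing``.  With both,
    ``cfg.prefer`` decides which is authoritative; the other is kept on
    the call for reporting.
    """
    if score is None and label is None:
        return ToolCall(tool=tool, call=CallState.MISSING)

    low_conf = False
    label_state = None
    if label is not None:
        label_state, low_conf = cfg.label_call(tool, label)

    if score is not None and (label is None or cfg.prefer == "score"):
        state = (
            CallState.SIGNIFICANT
            if cfg.score_significant(tool, score)
            else CallState.NOT_SIGNIFICANT
        )
    else:
        state = label_state

    return ToolCall(
        tool=tool, call=state, score=score, label=label, low_confidence=low_conf
    )


@dataclass
class ProfileLoadResult:
    """Profiles parsed from a dialect TSV plus a row-level error report."""

    profiles: list
    errors: list  # (row_index, message)

    def raise_on_errors(self) -> "ProfileLoadResult":
        if self.errors:
            detail = "; ".join(f"row {i}: {msg}" for i, msg in self.errors)
            raise ValueError(f"profile TSV had malformed rows: {detail}")
        return self


def load_profiles(
    path, cfg: ThresholdConfig = DEFAULT_THRESHOLDS
) -> ProfileLoadResult:
    """Load PredictionProfiles from a profile-dialect TSV.

    Every tool cell is resolved through :func:`classify`.  Malformed
    rows are collected into ``errors`` rather than silently skipped.
    """
    df = read_profile_table(path)
    profiles: list[PredictionProfile] = []
    errors: list[tuple] = []
    resolver = lambda tool, score, label: classify(tool, score, label, cfg)
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            profiles.append(row_to_profile(row, resolver))
        except (ValueError, KeyError) as exc:
            errors.append((i, str(exc)))
    return ProfileLoadResult(profiles=profiles, errors=errors)
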