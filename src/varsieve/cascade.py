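"""Staged prioritization of candidate deleterious nsSNPs.

Stages, applied in order with survivor sets nested:

1. consensus — the configured voting model calls the variant
   deleterious (skipped when the input set is already
   consensus-selected);
2. conservation — ConSurf grade >= 7 (highly conserved residue);
3. stability — predicted stability decrease with reliability index
   >= 5 (low-RI predictions are treated as unreliable and dropped,
   regardless of ddG);
4. structure — the mutant model shares the native fold: TM-score
   > 0.5 and RMSD < 6.5 A.

Variants surviving all gates form the shortlist, annotated (never
eliminated) with the MutPred2 pathogenicity tier and ModPred PTM
confidence.  Every variant gets a full trace: a fail at stage k leaves
all later stages not_evaluated, and evidence absent at a stage is
reported as not_evaluated rather than failed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .consensus import Decision, MissingPolicy, apply_model
from .types import (
    ConservationClass,
    DdgClass,
    ModPredCall,
    MutPredCall,
    PredictionProfile,
    StabilityDirection,
    mutpred_tier,
)

__all__ = [
    "CascadeConfig",
    "StageStatus",
    "CascadeTrace",
    "CascadeResult",
    "stage_conservation",
    "stage_stability",
    "stage_structure",
    "run_cascade",
]

STAGES = ("consensus", "conservation", "stability", "structure")


class StageStatus(enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds for every cascade stage.

    ``consensus_model=None`` declares the input already
    consensus-selected and skips stage 1.
    """

    consensus_model: Optional[str] = "D"
    missing_policy: MissingPolicy = MissingPolicy.STRICT
    conservation_min_grade: int = 7
    stability_min_ri: int = 5
    stability_gate: str = "direction"  # or "ddg_class"
    tm_score_min: float = 0.5  # exclusive
    rmsd_max: float = 6.5  # exclusive
    mutpred_pathogenic_min: float = 0.5  # annotation, not a gate


@dataclass
class StageOutcome:
    status: StageStatus
    detail: str = ""


@dataclass
class CascadeTrace:
    """Per-variant record of which stage passed/failed and why."""

    rsid: str
    stages: dict = field(default_factory=dict)  # stage name -> StageOutcome
    shortlisted: bool = False
    mutpred_annotation: Optional[str] = None
    modpred_annotation: Optional[str] = None


def stage_conservation(profile: PredictionProfile, cfg: CascadeConfig) -> StageOutcome:
    if profile.conservation is None:
        return StageOutcome(StageStatus.NOT_EVALUATED, "no conservation call")
    grade = profile.conservation.score
    if grade >= cfg.conservation_min_grade:
        return StageOutcome(StageStatus.PASS, f"grade {grade}")
    return StageOutcome(
        StageStatus.FAIL,
        f"grade {grade} < {cfg.conservation_min_grade} "
        f"({profile.conservation.klass.value})",
    )


def stage_stability(profile: PredictionProfile, cfg: CascadeConfig) -> StageOutcome:
    st = profile.stability
    if st is None:
        return StageOutcome(StageStatus.NOT_EVALUATED, "no stability call")
    if cfg.stability_gate == "direction":
        destabilizing = st.direction is StabilityDirection.DECREASE
    elif cfg.stability_gate == "ddg_class":
        destabilizing = st.ddg_class is DdgClass.DESTABILIZING
    else:
        raise ValueError(f"unknown stability gate {cfg.stability_gate!r}")
    if not destabilizing:
        return StageOutcome(
            StageStatus.FAIL, f"not destabilizing (ddG {st.ddg:+.2f})"
        )
    if st.ri < cfg.stability_min_ri:
        return StageOutcome(
            StageStatus.FAIL, f"RI {st.ri} < {cfg.stability_min_ri}"
        )
    return StageOutcome(StageStatus.PASS, f"decrease, ddG {st.ddg:+.2f}, RI {st.ri}")


def stage_structure(profile: PredictionProfile, cfg: CascadeConfig) -> StageOutcome:
    s = profile.structure
    if s is None:
        return StageOutcome(StageStatus.NOT_EVALUATED, "no structure call")
    if s.tm_score <= cfg.tm_score_min:
        return StageOutcome(
            StageStatus.FAIL, f"TM-score {s.tm_score} <= {cfg.tm_score_min}"
        )
    if s.rmsd >= cfg.rmsd_max:
        return StageOutcome(
            StageStatus.FAIL, f"RMSD {s.rmsd} >= {cfg.rmsd_max}"
        )
    return StageOutcome(
        StageStatus.PASS, f"TM-score {s.tm_score}, RMSD {s.rmsd}"
    )


def _stage_consensus(profile: PredictionProfile, cfg: CascadeConfig) -> StageOutcome:
    decision = apply_model(profile, cfg.consensus_model, cfg.missing_policy)
    if decision.decision is Decision.DELETERIOUS:
        return StageOutcome(StageStatus.PASS, decision.reason)
    if decision.decision is Decision.NOT_EVALUATED:
        return StageOutcome(StageStatus.NOT_EVALUATED, decision.reason)
    return StageOutcome(StageStatus.FAIL, decision.reason)


def _annotate(trace: CascadeTrace, profile: PredictionProfile, cfg: CascadeConfig) -> None:
    if profile.mutpred is not None:
        mp: MutPredCall = profile.mutpred
        verdict = (
            "pathogenic" if mp.score >= cfg.mutpred_pathogenic_min else "benign"
        )
        tiers = [
            f"{mech} [{tier.value}]" for mech, _p, tier in mp.feature_tiers()
        ]
        trace.mutpred_annotation = f"score {mp.score:.2f} ({verdict})" + (
            "; " + "; ".join(tiers) if tiers else ""
        )
    if profile.modpred is not None:
        md: ModPredCall = profile.modpred
        trace.modpred_annotation = (
            f"{md.ptm_type} score {md.score:.2f} "
            f"({md.confidence().value} confidence)"
        )


@dataclass
class CascadeResult:
    traces: list
    survivor_counts: dict  # stage name -> count surviving through it
    shortlist: list  # rsids

    @property
    def n_input(self) -> int:
        return len(self.traces)


def run_cascade(
    profiles: Sequence[PredictionProfile],
    cfg: CascadeConfig = CascadeConfig(),
) -> CascadeResult:
    """Run every profile through the staged filters.

    Survivor counts are nested by construction; a variant whose
    evidence is absent at a stage stops there as ``not_evaluated`` and
    does not survive, but its trace distinguishes this from a failed
    check.
    """
    stage_fns = {
        "consensus": _stage_consensus,
        "conservation": stage_conservation,
        "stability": stage_stability,
        "structure": stage_structure,
    }
    active_stages = [
        s for s in STAGES if not (s == "consensus" and cfg.consensus_model is None)
    ]

    traces: list[CascadeTrace] = []
    survivor_counts = {s: 0 for s in active_stages}
    shortlist: list[str] = []

    for profile in profiles:
        trace = CascadeTrace(rsid=profile.rsid)
        alive = True
        for stage in active_stages:
            if not alive:
                trace.stages[stage] = StageOutcome(
                    StageStatus.NOT_EVALUATED, "eliminated upstream"
                )
                continue
            outcome = stage_fns[stage](profile, cfg)
            trace.stages[stage] = outcome
            if outcome.status is StageStatus.PASS:
                survivor_counts[stage] += 1
            else:
                alive = False
        if alive:
            trace.shortlisted = True
            shortlist.append(profile.rsid)
            _annotate(trace, profile, cfg)
        traces.append(trace)

    return CascadeResult(
        traces=traces, survivor_counts=survivor_counts, shortlist=shortlist
    )
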