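"""k-of-5 consensus voting models for variant pathogenicity.

Eight models turn a per-variant evidence profile into a
deleterious/benign prediction.  Models A-D call a variant deleterious
when at least 1-4 of the five functional predictors are significant;
models A3-D3 additionally require the variant to sit at a conserved
residue (ConSurf grade >= 7) and to destabilize the protein (predicted
stability decrease).

Missing predictor outputs are governed by a policy:

- ``strict`` (default): a missing call is no evidence and counts
  against the vote (the denominator stays 5);
- ``permissive``: a missing call counts as significant;
- ``fraction``: the vote threshold is rescaled to the available calls,
  requiring n_significant / (5 - n_missing) >= min_votes / 5.

`ConsensusClassifier` wraps a model as a scikit-learn estimator so the
voting rule composes with sklearn model selection; `apply_model` /
`rank_models` are the functional interface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .types import (
    CallState,
    ConfusionCounts,
    ConservationClass,
    PredictionProfile,
    StabilityDirection,
    DdgClass,
    TruthLabel,
)

__all__ = [
    "MissingPolicy",
    "ConsensusModelSpec",
    "MODELS",
    "VoteSummary",
    "ConsensusDecision",
    "count_votes",
    "apply_model",
    "rank_models",
    "ConsensusClassifier",
]

N_TOOLS = 5


class MissingPolicy(enum.Enum):
    STRICT = "strict"
    PERMISSIVE = "permissive"
    FRACTION = "fraction"


@dataclass(frozen=True)
class ConsensusModelSpec:
    """One voting model: a minimum vote count plus optional
    conservation and stability gates (the X3 variants)."""

    id: str
    min_votes: int
    require_conservation: bool = False
    require_stability: bool = False
    # "direction": stability gate passes on a predicted decrease;
    # "ddg_class": gate passes only on ddG < -0.5 (destabilizing class).
    stability_gate: str = "direction"

    def __post_init__(self) -> None:
        if not 1 <= self.min_votes <= N_TOOLS:
            raise ValueError(f"min_votes {self.min_votes} outside 1-{N_TOOLS}")
        if self.require_conservation != self.require_stability:
            raise ValueError(
                "conservation and stability gates are enabled together "
                "(the X3 models) or not at all (A-D)"
            )


MODELS: Mapping[str, ConsensusModelSpec] = {
    spec.id: spec
    for spec in [
        ConsensusModelSpec("A", 1),
        ConsensusModelSpec("B", 2),
        ConsensusModelSpec("C", 3),
        ConsensusModelSpec("D", 4),
        ConsensusModelSpec("A3", 1, True, True),
        ConsensusModelSpec("B3", 2, True, True),
        ConsensusModelSpec("C3", 3, True, True),
        ConsensusModelSpec("D3", 4, True, True),
    ]
}


@dataclass(frozen=True)
class VoteSummary:
    """Raw per-tool call counts (always summing to 5) plus the policy
    used to interpret missing calls."""

    n_significant: int
    n_not_significant: int
    n_missing: int
    policy: MissingPolicy

    def __post_init__(self) -> None:
        if self.n_significant + self.n_not_significant + self.n_missing != N_TOOLS:
            raise ValueError("vote counts must sum to 5")

    @property
    def effective_significant(self) -> int:
        """Significant count after the policy folds missing calls."""
        if self.policy is MissingPolicy.PERMISSIVE:
            return self.n_significant + self.n_missing
        return self.n_significant

    def meets(self, min_votes: int) -> bool:
        """Does the vote clear ``min_votes`` under this policy?"""
        if self.policy is MissingPolicy.FRACTION:
            available = N_TOOLS - self.n_missing
            if available == 0:
                return False
            # n_sig / available >= min_votes / 5, in integer arithmetic
            return self.n_significant * N_TOOLS >= min_votes * available
        return self.effective_significant >= min_votes


def count_votes(
    profile: PredictionProfile,
    policy: MissingPolicy = MissingPolicy.STRICT,
) -> VoteSummary:
    """Tally the five functional calls of a profile."""
    n_sig = n_not = n_miss = 0
    for call in profile.functional_calls:
        if call.call is CallState.SIGNIFICANT:
            n_sig += 1
        elif call.call is CallState.NOT_SIGNIFICANT:
            n_not += 1
        else:
            n_miss += 1
    return VoteSummary(n_sig, n_not, n_miss, policy)


class Decision(enum.Enum):
    DELETERIOUS = "deleterious"
    BENIGN = "benign"
    NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class ConsensusDecision:
    """A model's verdict for one variant, with the full rationale."""

    rsid: str
    model_id: str
    votes: VoteSummary
    decision: Decision
    vote_passed: bool
    conservation_passed: Optional[bool] = None  # None = gate not required
    stability_passed: Optional[bool] = None
    reason: str = ""


def _stability_gate(profile: PredictionProfile, spec: ConsensusModelSpec) -> bool:
    st = profile.stability
    if spec.stability_gate == "direction":
        return st.direction is StabilityDirection.DECREASE
    if spec.stability_gate == "ddg_class":
        return st.ddg_class is DdgClass.DESTABILIZING
    raise ValueError(f"unknown stability gate {spec.stability_gate!r}")


def apply_model(
    profile: PredictionProfile,
    model: ConsensusModelSpec | str,
    policy: MissingPolicy = MissingPolicy.STRICT,
) -> ConsensusDecision:
    """Apply one consensus model to one profile.

    X3 models need conservation and stability evidence; without it the
    decision is ``not_evaluated`` (distinct from benign) with a reason.
    """
    spec = MODELS[model] if isinstance(model, str) else model
    votes = count_votes(profile, policy)
    vote_passed = votes.meets(spec.min_votes)

    conservation_passed: Optional[bool] = None
    stability_passed: Optional[bool] = None

    if spec.require_conservation or spec.require_stability:
        missing = []
        if profile.conservation is None:
            missing.append("conservation")
        if profile.stability is None:
            missing.append("stability")
        if missing:
            return ConsensusDecision(
                rsid=profile.rsid,
                model_id=spec.id,
                votes=votes,
                decision=Decision.NOT_EVALUATED,
                vote_passed=vote_passed,
                reason="missing evidence: " + ", ".join(missing),
            )
        conservation_passed = (
            profile.conservation.klass is ConservationClass.CONSERVED
        )
        stability_passed = _stability_gate(profile, spec)

    deleterious = vote_passed
    if conservation_passed is not None:
        deleterious = deleterious and conservation_passed
    if stability_passed is not None:
        deleterious = deleterious and stability_passed

    return ConsensusDecision(
        rsid=profile.rsid,
        model_id=spec.id,
        votes=votes,
        decision=Decision.DELETERIOUS if deleterious else Decision.BENIGN,
        vote_passed=vote_passed,
        conservation_passed=conservation_passed,
        stability_passed=stability_passed,
        reason=(
            f"{votes.n_significant}/{N_TOOLS} significant, "
            f"{votes.n_missing} missing"
        ),
    )


def rank_models(
    profiles: Sequence[PredictionProfile],
    truth_labels: Sequence[TruthLabel],
    model_list: Iterable[ConsensusModelSpec | str] = tuple(MODELS),
    policy: MissingPolicy = MissingPolicy.STRICT,
) -> dict[str, ConfusionCounts]:
    """Confusion counts per model against a labeled truth.

    Every profile receives a binary prediction (a ``not_evaluated`` X3
    decision counts as benign) so TP+FN and TN+FP stay fixed at the
    class sizes for every model.
    """
    if len(profiles) != len(truth_labels):
        raise ValueError("profiles and truth_labels must align")
    for label in truth_labels:
        if not isinstance(label, TruthLabel):
            raise ValueError(f"unlabeled or mislabeled profile: {label!r}")

    out: dict[str, ConfusionCounts] = {}
    for model in model_list:
        spec = MODELS[model] if isinstance(model, str) else model
        tp = fn = tn = fp = 0
        for profile, truth in zip(profiles, truth_labels):
            decision = apply_model(profile, spec, policy)
            predicted_deleterious = decision.decision is Decision.DELETERIOUS
            if truth is TruthLabel.PATHOGENIC:
                tp += predicted_deleterious
                fn += not predicted_deleterious
            else:
                fp += predicted_deleterious
                tn += not predicted_deleterious
        out[spec.id] = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    return out


class ConsensusClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn wrapper around one consensus voting model.

    Parameters
    ----------
    model : str, default="D"
        One of A, B, C, D (1-4 of 5 votes) or A3, B3, C3, D3 (same
        vote rule plus conservation and destabilization gates).
    missing_policy : str, default="strict"
        How missing predictor calls enter the vote; see module docs.

    The estimator is rule-based: ``fit`` validates input and records
    ``classes_``; no parameter is learned.  ``X`` is a sequence of
    :class:`~varsieve.types.PredictionProfile`.

    Examples
    --------
    >>> clf = ConsensusClassifier(model="D").fit(profiles, truth)
    >>> clf.predict(profiles[:2])
    array(['deleterious', 'benign'], dtype='<U11')
    """

    def __init__(self, model: str = "D", missing_policy: str = "strict"):
        self.model = model
        self.missing_policy = missing_policy

    def _spec(self) -> tuple[ConsensusModelSpec, MissingPolicy]:
        try:
            spec = MODELS[self.model]
        except KeyError:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(MODELS)}"
            ) from None
        return spec, MissingPolicy(self.missing_policy)

    def fit(self, X, y=None):
        spec, policy = self._spec()
        for profile in X:
            if not isinstance(profile, PredictionProfile):
                raise TypeError(
                    "X must be a sequence of PredictionProfile, got "
                    f"{type(profile).__name__}"
                )
        self.classes_ = np.array(["benign", "deleterious"])
        self.n_features_in_ = 1
        self.spec_ = spec
        self.policy_ = policy
        return self

    def decide(self, X) -> list[ConsensusDecision]:
        """Full per-variant decisions with vote breakdowns."""
        check_is_fitted(self, "spec_")
        return [apply_model(p, self.spec_, self.policy_) for p in X]

    def predict(self, X):
        decisions = self.decide(X)
        return np.array(
            [
                "deleterious" if d.decision is Decision.DELETERIOUS else "benign"
                for d in decisions
            ]
        )

    def score(self, X, y):
        """Fraction of exact label matches ('deleterious'/'benign')."""
        y = np.asarray(
            [v.value if isinstance(v, TruthLabel) else str(v) for v in y]
        )
        y = np.where(y == "pathogenic", "deleterious", y)
        return float(np.mean(self.predict(X) == y))
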