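"""Sensitivity / specificity / accuracy for the model benchmark.

Se = TP/(TP+FN) x 100, Sp = TN/(TN+FP) x 100,
Ac = (TP+TN)/(TP+TN+FP+FN) x 100.

Arithmetic is exact (``fractions.Fraction``) up to the final float; an
empty class yields ``None`` (undefined), never 0 or 100.  Display
rounding is half-to-even at one decimal and applied only at the edge.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Optional, Sequence

import pandas as pd

from .consensus import MODELS, MissingPolicy, rank_models
from .types import BenchmarkRecord, ConfusionCounts, MetricsReport

__all__ = [
    "sensitivity",
    "specificity",
    "accuracy",
    "metrics_report",
    "evaluate",
]


def _percent(numerator: int, denominator: int) -> Optional[float]:
    if denominator == 0:
        return None
    return float(Fraction(numerator, denominator) * 100)


def sensitivity(c: ConfusionCounts) -> Optional[float]:
    """True-positive rate as a percentage; None if no positives."""
    return _percent(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> Optional[float]:
    """True-negative rate as a percentage; None if no negatives."""
    return _percent(c.tn, c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> Optional[float]:
    """Correct predictions over all predictions, as a percentage."""
    return _percent(c.tp + c.tn, c.total)


def metrics_report(c: ConfusionCounts) -> MetricsReport:
    return MetricsReport(
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        accuracy=accuracy(c),
    )


def evaluate(
    records: Sequence[BenchmarkRecord],
    models: Iterable[str] = tuple(MODELS),
    policy: MissingPolicy = MissingPolicy.STRICT,
) -> pd.DataFrame:
    """Benchmark the consensus models on a labeled standard dataset.

    Returns one row per model: confusion counts plus Se/Sp/Ac.
    Duplicate variant ids are an error (a duplicated record would tilt
    the class sizes silently).
    """
    ids = [r.variant_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate variant ids in benchmark: {dupes}")

    profiles = [r.profile for r in records]
    truths = [r.truth for r in records]
    counts = rank_models(profiles, truths, models, policy)

    rows = []
    for model_id, c in counts.items():
        rows.append(
            {
                "model": model_id,
                "tp": c.tp,
                "fn": c.fn,
                "tn": c.tn,
                "fp": c.fp,
                "sensitivity": sensitivity(c),
                "specificity": specificity(c),
                "accuracy": accuracy(c),
            }
        )
    return pd.DataFrame(rows)


def counts_to_metrics_table(counts: dict[str, ConfusionCounts]) -> pd.DataFrame:
    """Render precomputed per-model confusion counts as a metrics table."""
    rows = []
    for model_id, c in counts.items():
        rows.append(
            {
                "model": model_id,
                "tp": c.tp,
                "fn": c.fn,
                "tn": c.tn,
                "fp": c.fp,
                "sensitivity": sensitivity(c),
                "specificity": specificity(c),
                "accuracy": accuracy(c),
            }
        )
    return pd.DataFrame(rows)
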