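"""Synthetic inputs with controlled statistical structure.

Two generators make every pipeline stage testable without external
downloads:

``generate_benchmark``
    A labeled standard dataset of pathogenic/benign variants.  Each
    tool's score is drawn from a class-conditional two-region mixture:
    with probability ``separation`` the score falls in the region that
    agrees with the truth label (e.g. a pathogenic variant's SIFT score
    lands in [0, 0.05]), otherwise in the disagreeing region.
    ``separation`` is therefore the marginal per-tool accuracy;
    1.0 gives a fully separable dataset.  Conservation and stability
    evidence follow the same scheme.

``generate_vcf``
    A small cohort VCF: genotypes drawn from Hardy-Weinberg proportions
    at per-site allele frequencies, site depth/quality drawn so that a
    configurable fraction of sites fail the quality filter, plus a
    truth table of which sites a matcher should recover.

One seed fans out to per-component substreams (numpy SeedSequence
spawning), so adding a tool does not perturb the other tools' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .thresholds import DEFAULT_THRESHOLDS, ThresholdConfig, classify
from .types import (
    BenchmarkRecord,
    ConservationCall,
    PredictionProfile,
    StabilityCall,
    StabilityDirection,
    StructureCall,
    Tool,
    TruthLabel,
)

__all__ = ["SyntheticSpec", "generate_benchmark", "generate_vcf", "DepthModel"]

# (damaging region, neutral region) per tool, on each tool's own scale.
_SCORE_REGIONS = {
    Tool.SIFT: ((0.0, 0.05), (0.06, 1.0)),
    Tool.POLYPHEN2: ((0.91, 1.0), (0.0, 0.9)),
    Tool.CONDEL: ((0.51, 1.0), (0.0, 0.5)),
    Tool.PROVEAN: ((-10.0, -2.5), (-2.4, 5.0)),
    Tool.PANTHER: ((455.0, 2000.0), (0.0, 450.0)),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic standard dataset.

    Defaults mirror a 50 pathogenic / 50 benign clinical validation
    set with per-tool marginal accuracy 0.85 — the regime where the
    1-of-5 .. 4-of-5 voting models visibly trade sensitivity for
    specificity.
    """

    n_pathogenic: int = 50
    n_benign: int = 50
    separation: float = 0.85
    #: per-tool missingness: a Tool -> rate mapping, or one rate for all
    missingness: object = field(default_factory=dict)
    evidence_accuracy: float = 0.85  # conservation/stability/structure
    with_evidence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must be in [0, 1]")
        if not 0.0 <= self.evidence_accuracy <= 1.0:
            raise ValueError("evidence_accuracy must be in [0, 1]")
        rates = (
            [self.missingness]
            if isinstance(self.missingness, (int, float))
            else list(self.missingness.values())
        )
        for rate in rates:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate {rate} outside [0, 1]")

    def missing_rate(self, tool: Tool) -> float:
        if isinstance(self.missingness, (int, float)):
            return float(self.missingness)
        return float(self.missingness.get(tool, 0.0))


def _tool_score(rng: np.random.Generator, tool: Tool, damaging: bool) -> float:
    lo, hi = _SCORE_REGIONS[tool][0 if damaging else 1]
    return float(rng.uniform(lo, hi))


def generate_benchmark(
    spec: SyntheticSpec = SyntheticSpec(),
    cfg: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> list[BenchmarkRecord]:
    """Draw a labeled benchmark dataset; reproducible given the seed."""
    ss = np.random.SeedSequence(spec.seed)
    streams = {
        tool: np.random.default_rng(child)
        for tool, child in zip(Tool, ss.spawn(len(Tool)))
    }
    evidence_rng = np.random.default_rng(ss.spawn(1)[0])

    labels = [TruthLabel.PATHOGENIC] * spec.n_pathogenic + [
        TruthLabel.BENIGN
    ] * spec.n_benign

    records: list[BenchmarkRecord] = []
    for i, truth in enumerate(labels):
        pathogenic = truth is TruthLabel.PATHOGENIC
        calls = []
        for tool in Tool:
            rng = streams[tool]
            missing_rate = spec.missing_rate(tool)
            # draw both decisions unconditionally to keep streams aligned
            is_missing = rng.random() < missing_rate
            agrees = rng.random() < spec.separation
            damaging = pathogenic if agrees else not pathogenic
            score = _tool_score(rng, tool, damaging)
            if is_missing:
                calls.append(classify(tool, cfg=cfg))
            else:
                calls.append(classify(tool, score=score, cfg=cfg))

        conservation = stability = structure = None
        if spec.with_evidence:
            agrees = evidence_rng.random() < spec.evidence_accuracy
            conserved = pathogenic if agrees else not pathogenic
            grade = (
                int(evidence_rng.integers(7, 10))
                if conserved
                else int(evidence_rng.integers(1, 7))
            )
            conservation = ConservationCall(grade)

            agrees = evidence_rng.random() < spec.evidence_accuracy
            destabilizing = pathogenic if agrees else not pathogenic
            stability = StabilityCall(
                direction=(
                    StabilityDirection.DECREASE
                    if destabilizing
                    else StabilityDirection.INCREASE
                ),
                ddg=float(
                    evidence_rng.uniform(-2.5, -0.6)
                    if destabilizing
                    else evidence_rng.uniform(-0.4, 1.5)
                ),
                ri=int(evidence_rng.integers(5, 11)),
            )

            agrees = evidence_rng.random() < spec.evidence_accuracy
            same_fold = (not pathogenic) if agrees else pathogenic
            structure = StructureCall(
                tm_score=float(
                    evidence_rng.uniform(0.55, 1.0)
                    if same_fold
                    else evidence_rng.uniform(0.0, 0.45)
                ),
                rmsd=float(evidence_rng.uniform(0.5, 6.0)),
            )

        profile = PredictionProfile(
            rsid=f"rsS{i:04d}",
            gene=f"GENE{i:04d}",
            aa_change=None,
            functional_calls=tuple(calls),
            conservation=conservation,
            stability=stability,
            structure=structure,
        )
        records.append(
            BenchmarkRecord(variant_id=profile.rsid, truth=truth, profile=profile)
        )
    return records


@dataclass(frozen=True)
class DepthModel:
    """Site depth/quality model for VCF simulation.

    A ``fail_fraction`` of sites is forced below the quality filter
    (half by depth, half by quality); passing sites draw depth from a
    Poisson around ``mean_depth`` (floored at the filter bound) and
    quality from a normal around ``mean_qual``.
    """

    mean_depth: float = 30.0
    mean_qual: float = 60.0
    fail_fraction: float = 0.0
    min_pass_depth: int = 5
    min_pass_qual: float = 30.0
    fixed_depth: Optional[int] = None  # overrides everything when set


def generate_vcf(
    sites: Sequence[tuple],
    population_afs: Sequence[float],
    n_samples: int,
    depth_model: DepthModel = DepthModel(),
    seed: int = 0,
) -> tuple[str, pd.DataFrame]:
    """Emit VCF v4.2 text plus a truth table.

    ``sites`` is a sequence of (chrom, pos, ref, alt, rsid); genotypes
    are Hardy-Weinberg draws at the matching allele frequency.  The
    truth table records per site the drawn AF, whether the site passes
    the default-style quality filter, whether the alt allele was
    observed, and hence whether a matcher should recover it.
    """
    if len(sites) != len(population_afs):
        raise ValueError("sites and population_afs must align")
    for af in population_afs:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0, 1]")

    ss = np.random.SeedSequence(seed)
    gt_rng, qc_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"S{i:03d}" for i in range(n_samples)),
    ]
    body = []
    truth_rows = []
    for (chrom, pos, ref, alt, rsid), af in zip(sites, population_afs):
        genotypes = gt_rng.choice(
            ["0/0", "0/1", "1/1"],
            size=n_samples,
            p=[(1 - af) ** 2, 2 * af * (1 - af), af**2],
        )
        if depth_model.fixed_depth is not None:
            depth = depth_model.fixed_depth
            qual = depth_model.mean_qual
        elif qc_rng.random() < depth_model.fail_fraction:
            if qc_rng.random() < 0.5:
                depth = int(qc_rng.integers(0, depth_model.min_pass_depth))
                qual = depth_model.mean_qual
            else:
                depth = max(
                    depth_model.min_pass_depth,
                    int(qc_rng.poisson(depth_model.mean_depth)),
                )
                qual = float(qc_rng.uniform(1.0, depth_model.min_pass_qual - 1.0))
        else:
            depth = max(
                depth_model.min_pass_depth,
                int(qc_rng.poisson(depth_model.mean_depth)),
            )
            qual = max(
                depth_model.min_pass_qual,
                float(qc_rng.normal(depth_model.mean_qual, 5.0)),
            )
        body.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t{qual:.1f}\tPASS\t"
            f"DP={depth}\tGT\t" + "\t".join(genotypes)
        )
        alt_count = sum(gt.count("1") for gt in genotypes)
        passes = depth >= depth_model.min_pass_depth and qual >= depth_model.min_pass_qual
        truth_rows.append(
            {
                "rsid": rsid,
                "chrom": chrom,
                "pos": pos,
                "target_af": af,
                "empirical_af": alt_count / (2 * n_samples),
                "passes_quality": passes,
                "alt_observed": alt_count > 0,
                "should_match": passes and alt_count > 0,
            }
        )
    return "\n".join(header + body) + "\n", pd.DataFrame(truth_rows)
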