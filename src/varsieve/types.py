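"""Core domain types for consensus variant-pathogenicity prediction.

The pipeline reasons about nonsynonymous SNPs (nsSNPs): coding variants
that substitute one amino acid.  Each variant accumulates evidence from
five functional-effect predictors (SIFT, PolyPhen-2, Condel, PROVEAN,
PANTHER), an evolutionary-conservation grade (ConSurf, 1-9), a protein
stability prediction (I-Mutant: direction, ddG in kcal/mol, reliability
index 0-10), a structural comparison of native vs mutant models
(TM-score, RMSD), and functional annotations (MutPred2 pathogenicity
score, ModPred PTM-site confidence).  Everything downstream — the
consensus voting models, the benchmark metrics, the prioritization
cascade — consumes these types.

Validation is deliberately non-throwing where the pipeline needs a
report rather than an exception: :func:`validate_profile` returns a list
of human-readable violations.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "AMINO_ACIDS",
    "AminoAcidChange",
    "BenchmarkRecord",
    "ConfusionCounts",
    "ConsequenceClass",
    "ConservationCall",
    "CallState",
    "GwasAssociation",
    "MetricsReport",
    "ModPredCall",
    "MutPredCall",
    "PredictionProfile",
    "StabilityCall",
    "StructureCall",
    "Tool",
    "ToolCall",
    "UnclassifiedConsequenceError",
    "parse_consequence",
    "validate_profile",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_AA_CHANGE_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class Tool(enum.Enum):
    """The five functional-effect predictors that vote in the consensus."""

    SIFT = "SIFT"
    POLYPHEN2 = "POLYPHEN2"
    CONDEL = "CONDEL"
    PROVEAN = "PROVEAN"
    PANTHER = "PANTHER"


class CallState(enum.Enum):
    SIGNIFICANT = "significant"
    NOT_SIGNIFICANT = "not_significant"
    MISSING = "missing"


class ConsequenceClass(enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    UTR3 = "utr3"
    UTR5 = "utr5"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    STOP_GAINED = "stop_gained"
    SPLICE_REGION = "splice_region"
    SPLICE_ACCEPTOR = "splice_acceptor"
    REGULATORY = "regulatory"
    TFBS = "tfbs"
    NONCODING_TRANSCRIPT = "noncoding_transcript"
    INFRAME_INSERTION = "inframe_insertion"
    CODING_OTHER = "coding_other"


class UnclassifiedConsequenceError(ValueError):
    """Raised for consequence strings that map to no known class."""


#: Common annotation-dialect spellings (VEP/SO terms and loose variants)
#: mapped onto the closed enumeration.  Unknown strings raise; they are
#: never silently coerced.
CONSEQUENCE_ALIASES = {
    "nonsynonymous": ConsequenceClass.NONSYNONYMOUS,
    "missense": ConsequenceClass.NONSYNONYMOUS,
    "missense_variant": ConsequenceClass.NONSYNONYMOUS,
    "nssnp": ConsequenceClass.NONSYNONYMOUS,
    "synonymous": ConsequenceClass.SYNONYMOUS,
    "synonymous_variant": ConsequenceClass.SYNONYMOUS,
    "ssnp": ConsequenceClass.SYNONYMOUS,
    "utr3": ConsequenceClass.UTR3,
    "3_prime_utr_variant": ConsequenceClass.UTR3,
    "3'utr": ConsequenceClass.UTR3,
    "utr5": ConsequenceClass.UTR5,
    "5_prime_utr_variant": ConsequenceClass.UTR5,
    "5'utr": ConsequenceClass.UTR5,
    "intronic": ConsequenceClass.INTRONIC,
    "intron_variant": ConsequenceClass.INTRONIC,
    "intergenic": ConsequenceClass.INTERGENIC,
    "intergenic_variant": ConsequenceClass.INTERGENIC,
    "stop_gained": ConsequenceClass.STOP_GAINED,
    "splice_region": ConsequenceClass.SPLICE_REGION,
    "splice_region_variant": ConsequenceClass.SPLICE_REGION,
    "splice_acceptor": ConsequenceClass.SPLICE_ACCEPTOR,
    "splice_acceptor_variant": ConsequenceClass.SPLICE_ACCEPTOR,
    "regulatory": ConsequenceClass.REGULATORY,
    "regulatory_region_variant": ConsequenceClass.REGULATORY,
    "tfbs": ConsequenceClass.TFBS,
    "tf_binding_site_variant": ConsequenceClass.TFBS,
    "noncoding_transcript": ConsequenceClass.NONCODING_TRANSCRIPT,
    "non_coding_transcript_variant": ConsequenceClass.NONCODING_TRANSCRIPT,
    "inframe_insertion": ConsequenceClass.INFRAME_INSERTION,
    "coding_other": ConsequenceClass.CODING_OTHER,
    "coding_sequence_variant": ConsequenceClass.CODING_OTHER,
}


def parse_consequence(text: str) -> ConsequenceClass:
    """Map an annotation string onto the closed consequence enumeration.

    Raises
    ------
    UnclassifiedConsequenceError
        If the string matches no known spelling.  Unknown inputs are a
        loud error, never a silent default.
    """
    key = text.strip().lower().replace(" ", "_")
    try:
        return CONSEQUENCE_ALIASES[key]
    except KeyError:
        raise UnclassifiedConsequenceError(
            f"unclassified consequence {text!r}; known spellings: "
            + ", ".join(sorted(CONSEQUENCE_ALIASES))
        ) from None


@dataclass(frozen=True)
class AminoAcidChange:
    """A single-residue substitution, e.g. R402Q."""

    ref: str
    pos: int
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in AMINO_ACIDS or self.alt not in AMINO_ACIDS:
            raise ValueError(
                f"invalid amino-acid code in {self.ref}{self.pos}{self.alt}"
            )
        if self.pos < 1:
            raise ValueError(f"residue position must be >= 1, got {self.pos}")

    @classmethod
    def parse(cls, text: str) -> "AminoAcidChange":
        """Parse the compact 'R402Q' form (case-insensitive)."""
        m = _AA_CHANGE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse amino-acid change {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)), m.group(3).upper())

    def __str__(self) -> str:
        return f"{self.ref}{self.pos}{self.alt}"


@dataclass(frozen=True)
class GwasAssociation:
    """One catalog row: a variant, the trait it is associated with, and
    its gene/protein context on GRCh37 (1-based coordinates)."""

    rsid: str
    chrom: str
    pos: int
    trait: str
    gene: str
    consequence: ConsequenceClass
    risk_allele: Optional[str] = None
    risk_allele_freq: Optional[float] = None
    protein_accession: Optional[str] = None
    aa_change: Optional[AminoAcidChange] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        if self.risk_allele_freq is not None and not (
            0.0 <= self.risk_allele_freq <= 1.0
        ):
            raise ValueError(
                f"{self.rsid}: risk allele frequency "
                f"{self.risk_allele_freq} outside [0, 1]"
            )


@dataclass(frozen=True)
class ToolCall:
    """One predictor's verdict: raw score and/or label, resolved to a
    significant / not_significant / missing call."""

    tool: Tool
    call: CallState
    score: Optional[float] = None
    label: Optional[str] = None
    low_confidence: bool = False

    @property
    def consistent(self) -> bool:
        """call is 'missing' exactly when both score and label are absent."""
        absent = self.score is None and self.label is None
        return absent == (self.call is CallState.MISSING)


class ConservationClass(enum.Enum):
    VARIABLE = "variable"
    INTERMEDIATE = "intermediate"
    CONSERVED = "conserved"


@dataclass(frozen=True)
class ConservationCall:
    """ConSurf evolutionary-conservation grade: 1-4 variable,
    5-6 intermediate, 7-9 conserved."""

    score: int

    @property
    def klass(self) -> ConservationClass:
        if self.score <= 4:
            return ConservationClass.VARIABLE
        if self.score <= 6:
            return ConservationClass.INTERMEDIATE
        return ConservationClass.CONSERVED


class StabilityDirection(enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"


class DdgClass(enum.Enum):
    DESTABILIZING = "destabilizing"
    STABILIZING = "stabilizing"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class StabilityCall:
    """I-Mutant stability prediction.

    ddG (kcal/mol) is mutant minus native unfolding free energy;
    below -0.5 destabilizing, above +0.5 stabilizing, else neutral.
    The reliability index (RI) runs 0-10, 10 most reliable.
    """

    direction: StabilityDirection
    ddg: float
    ri: int

    @property
    def ddg_class(self) -> DdgClass:
        if self.ddg < -0.5:
            return DdgClass.DESTABILIZING
        if self.ddg > 0.5:
            return DdgClass.STABILIZING
        return DdgClass.NEUTRAL


@dataclass(frozen=True)
class StructureCall:
    """Native-vs-mutant structural comparison: TM-score in [0, 1]
    (> 0.5 implies the same fold) and RMSD in Angstroms."""

    tm_score: float
    rmsd: float
    c_score: Optional[float] = None  # model-confidence annotation only


class HypothesisTier(enum.Enum):
    NONE = "none"
    ACTIONABLE = "actionable"
    CONFIDENT = "confident"
    VERY_CONFIDENT = "very_confident"


def mutpred_tier(g: float, p: float) -> HypothesisTier:
    """Tier a MutPred2 mechanism hypothesis from the general score g and
    the feature p-value: very confident (g > 0.75, p < 0.01),
    confident (g > 0.75, p < 0.05), actionable (g > 0.5, p < 0.05)."""
    if g > 0.75 and p < 0.01:
        return HypothesisTier.VERY_CONFIDENT
    if g > 0.75 and p < 0.05:
        return HypothesisTier.CONFIDENT
    if g > 0.5 and p < 0.05:
        return HypothesisTier.ACTIONABLE
    return HypothesisTier.NONE


@dataclass(frozen=True)
class MutPredCall:
    """MutPred2 output: general pathogenicity score g in [0, 1]
    (>= 0.5 pathogenic) plus mechanism hypotheses with p-values."""

    score: float
    features: tuple = ()  # ((mechanism, p_value), ...)

    @property
    def pathogenic(self) -> bool:
        return self.score >= 0.5

    def feature_tiers(self) -> tuple:
        return tuple(
            (mech, p, mutpred_tier(self.score, p)) for mech, p in self.features
        )


class ModPredConfidence(enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass(frozen=True)
class ModPredCall:
    """ModPred PTM-site prediction (e.g. proteolytic cleavage).

    Default tiering: < 0.7 low, 0.7-0.9 medium, >= 0.9 high.  The
    coarser historical scheme (> 0.5 high, = 0.5 medium, < 0.5 low) is
    available via ``confidence(scheme="coarse")``.
    """

    ptm_type: str
    score: float

    def confidence(self, scheme: str = "default") -> ModPredConfidence:
        if scheme == "default":
            if self.score >= 0.9:
                return ModPredConfidence.HIGH
            if self.score >= 0.7:
                return ModPredConfidence.MEDIUM
            return ModPredConfidence.LOW
        if scheme == "coarse":
            if self.score > 0.5:
                return ModPredConfidence.HIGH
            if self.score == 0.5:
                return ModPredConfidence.MEDIUM
            return ModPredConfidence.LOW
        raise ValueError(f"unknown ModPred tiering scheme {scheme!r}")


@dataclass(frozen=True)
class PredictionProfile:
    """All per-variant evidence: the five functional tool calls plus
    optional conservation, stability, structure and annotation calls.

    Absent optional evidence means the variant was *not evaluated* for
    that axis — downstream stages report this separately from a failed
    check.
    """

    rsid: str
    gene: str
    aa_change: Optional[AminoAcidChange]
    functional_calls: tuple  # five ToolCall, one per Tool
    conservation: Optional[ConservationCall] = None
    stability: Optional[StabilityCall] = None
    structure: Optional[StructureCall] = None
    mutpred: Optional[MutPredCall] = None
    modpred: Optional[ModPredCall] = None
    trait: Optional[str] = None

    def call_for(self, tool: Tool) -> ToolCall:
        for call in self.functional_calls:
            if call.tool is tool:
                return call
        raise KeyError(f"{self.rsid}: no call for {tool.value}")

    def with_evidence(self, **kwargs) -> "PredictionProfile":
        """Return a copy with conservation/stability/... attached."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP counts for one classifier against a labeled truth."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity, specificity and accuracy as percentages; ``None``
    marks an undefined metric (empty class), never 0 or 100."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} {v} outside [0, 100]")


class TruthLabel(enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


@dataclass(frozen=True)
class BenchmarkRecord:
    """One labeled variant of a validation standard dataset."""

    variant_id: str
    truth: TruthLabel
    profile: PredictionProfile


def validate_profile(profile: PredictionProfile) -> list[str]:
    """Check every type invariant of a profile; return violations.

    An empty list means the profile is valid.  Violations name the field
    and the rule broken.  Evidence dataclasses are deliberately
    constructible in an invalid state so that loaders can collect all
    problems into one report instead of dying on the first.
    """
    violations: list[str] = []

    seen: dict[Tool, int] = {}
    for call in profile.functional_calls:
        if not isinstance(call.tool, Tool):
            violations.append(f"functional_calls: unknown tool {call.tool!r}")
            continue
        seen[call.tool] = seen.get(call.tool, 0) + 1
    for tool, n in seen.items():
        if n > 1:
            violations.append(
                f"functional_calls: duplicate {tool.value} call ({n} entries)"
            )
    missing_tools = [t.value for t in Tool if t not in seen]
    if missing_tools:
        violations.append(
            "functional_calls: no call for " + ", ".join(missing_tools)
        )
    for call in profile.functional_calls:
        absent = call.score is None and call.label is None
        if absent != (call.call is CallState.MISSING):
            violations.append(
                f"functional_calls[{call.tool.value}]: call 'missing' must "
                "coincide with absent score and label"
            )

    if profile.aa_change is not None:
        aa = profile.aa_change
        if aa.ref not in AMINO_ACIDS or aa.alt not in AMINO_ACIDS:
            violations.append(f"aa_change: invalid residue code in {aa}")
        if aa.pos < 1:
            violations.append(f"aa_change: residue position {aa.pos} < 1")

    if profile.conservation is not None:
        if not 1 <= profile.conservation.score <= 9:
            violations.append(
                f"conservation: grade {profile.conservation.score} outside 1-9"
            )
    if profile.stability is not None:
        if not 0 <= profile.stability.ri <= 10:
            violations.append(
                f"stability: reliability index {profile.stability.ri} "
                "outside 0-10"
            )
    if profile.structure is not None:
        s = profile.structure
        if not 0.0 <= s.tm_score <= 1.0:
            violations.append(f"structure: TM-score {s.tm_score} outside [0, 1]")
        if s.rmsd < 0:
            violations.append(f"structure: RMSD {s.rmsd} negative")
    if profile.mutpred is not None and not 0.0 <= profile.mutpred.score <= 1.0:
        violations.append(
            f"mutpred: score {profile.mutpred.score} outside [0, 1]"
        )
    if profile.modpred is not None and not 0.0 <= profile.modpred.score <= 1.0:
        violations.append(
            f"modpred: score {profile.modpred.score} outside [0, 1]"
        )
    return violations
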