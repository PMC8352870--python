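"""Shared test helpers: profile builders and an independent
brute-force vote counter used as the oracle for the consensus engine.

The oracle deliberately re-derives the voting rules from first
principles (exact rational arithmetic over enumerated call states) and
never calls into varsieve.consensus.
"""

from __future__ import annotations

from fractions import Fraction

from varsieve.types import (
    CallState,
    ConservationCall,
    PredictionProfile,
    StabilityCall,
    StabilityDirection,
    Tool,
    ToolCall,
)

# a representative in-range score per tool and direction
_DAMAGING_SCORE = {
    Tool.SIFT: 0.01,
    Tool.POLYPHEN2: 0.99,
    Tool.CONDEL: 0.8,
    Tool.PROVEAN: -5.0,
    Tool.PANTHER: 800.0,
}
_NEUTRAL_SCORE = {
    Tool.SIFT: 0.5,
    Tool.POLYPHEN2: 0.2,
    Tool.CONDEL: 0.1,
    Tool.PROVEAN: 0.0,
    Tool.PANTHER: 100.0,
}


def make_call(tool: Tool, state: str) -> ToolCall:
    """state: 's' significant, 'n' not significant, 'm' missing."""
    if state == "m":
        return ToolCall(tool=tool, call=CallState.MISSING)
    if state == "s":
        return ToolCall(
            tool=tool, call=CallState.SIGNIFICANT, score=_DAMAGING_SCORE[tool]
        )
    return ToolCall(
        tool=tool, call=CallState.NOT_SIGNIFICANT, score=_NEUTRAL_SCORE[tool]
    )


def make_profile(
    states: str,
    rsid: str = "rsTEST",
    conserved: bool | None = None,
    destabilizing: bool | None = None,
    ri: int = 9,
) -> PredictionProfile:
    """Build a profile from a 5-char call-state string (SIFT,
    PolyPhen-2, Condel, PROVEAN, PANTHER order).  ``conserved`` /
    ``destabilizing`` None leaves that evidence absent."""
    assert len(states) == 5
    calls = tuple(make_call(tool, s) for tool, s in zip(Tool, states))
    conservation = None
    if conserved is not None:
        conservation = ConservationCall(9 if conserved else 3)
    stability = None
    if destabilizing is not None:
        stability = StabilityCall(
            direction=(
                StabilityDirection.DECREASE
                if destabilizing
                else StabilityDirection.INCREASE
            ),
            ddg=-1.2 if destabilizing else 0.8,
            ri=ri,
        )
    return PredictionProfile(
        rsid=rsid,
        gene="GENE",
        aa_change=None,
        functional_calls=calls,
        conservation=conservation,
        stability=stability,
    )


MIN_VOTES = {"A": 1, "B": 2, "C": 3, "D": 4, "A3": 1, "B3": 2, "C3": 3, "D3": 4}


def oracle_decision(
    states: str,
    model_id: str,
    policy: str,
    conserved: bool | None = None,
    destabilizing: bool | None = None,
) -> str:
    """Independent re-derivation of a consensus model's decision."""
    n_sig = states.count("s")
    n_miss = states.count("m")
    k = MIN_VOTES[model_id]

    if policy == "strict":
        vote = n_sig >= k
    elif policy == "permissive":
        vote = n_sig + n_miss >= k
    elif policy == "fraction":
        available = 5 - n_miss
        vote = available > 0 and Fraction(n_sig, available) >= Fraction(k, 5)
    else:
        raise ValueError(policy)

    if model_id.endswith("3"):
        if conserved is None or destabilizing is None:
            return "not_evaluated"
        return (
            "deleterious" if (vote and conserved and destabilizing) else "benign"
        )
    return "deleterious" if vote else "benign"
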