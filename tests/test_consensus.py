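"""Consensus voting engine: vote counting, the eight models, missing
policies, nesting properties, and the sklearn estimator wrapper."""

import itertools

import numpy as np
import pytest

from varsieve.consensus import (
    MODELS,
    ConsensusClassifier,
    Decision,
    MissingPolicy,
    apply_model,
    count_votes,
    rank_models,
)
from varsieve.fixtures import variant_profiles
from varsieve.types import TruthLabel
from helpers import make_profile, oracle_decision


class TestCountVotes:
    def test_published_candidate_with_four_votes(self):
        # labels Del, Prob_dam, Del, Neu, Prob_dam
        profile = make_profile("sssns", rsid="rs1126809")
        votes = count_votes(profile)
        assert votes.n_significant == 4
        assert votes.n_missing == 0

    def test_three_votes_one_missing(self):
        # labels Del, pos_dam, Del, Del, missing
        profile = make_profile("snssm", rsid="rs671")
        votes = count_votes(profile, MissingPolicy.STRICT)
        assert (votes.n_significant, votes.n_missing) == (3, 1)

    def test_all_missing_under_each_policy(self):
        profile = make_profile("mmmmm")
        strict = count_votes(profile, MissingPolicy.STRICT)
        permissive = count_votes(profile, MissingPolicy.PERMISSIVE)
        assert strict.effective_significant == 0
        assert permissive.effective_significant == 5

    def test_counts_always_sum_to_five(self):
        for states in itertools.product("snm", repeat=5):
            votes = count_votes(make_profile("".join(states)))
            assert votes.n_significant + votes.n_not_significant + votes.n_missing == 5


class TestApplyModel:
    def test_four_votes_passes_model_d(self):
        decision = apply_model(make_profile("sssns", rsid="rs1126809"), "D")
        assert decision.decision is Decision.DELETERIOUS

    def test_three_votes_fails_d_passes_c(self):
        profile = make_profile("snssm", rsid="rs671")
        assert apply_model(profile, "D").decision is Decision.BENIGN
        assert apply_model(profile, "C").decision is Decision.DELETERIOUS

    def test_five_votes_passes_model_d(self):
        decision = apply_model(make_profile("sssss", rsid="rs9379084"), "D")
        assert decision.decision is Decision.DELETERIOUS

    def test_x3_without_evidence_is_not_evaluated(self):
        decision = apply_model(make_profile("sssss"), "D3")
        assert decision.decision is Decision.NOT_EVALUATED
        assert "missing evidence" in decision.reason

    def test_x3_gates_are_conjunctive(self):
        passing = make_profile("sssss", conserved=True, destabilizing=True)
        assert apply_model(passing, "D3").decision is Decision.DELETERIOUS
        for conserved, destabilizing in [(False, True), (True, False), (False, False)]:
            profile = make_profile(
                "sssss", conserved=conserved, destabilizing=destabilizing
            )
            assert apply_model(profile, "D3").decision is Decision.BENIGN

    def test_neutral_ddg_still_passes_direction_gate(self):
        """The stability gate keys on the predicted direction, not the
        ddG class: a -0.48 kcal/mol decrease (neutral by ddG) passes."""
        profile = make_profile("sssss", conserved=True, destabilizing=True)
        profile = profile.with_evidence(
            stability=profile.stability.__class__(
                profile.stability.direction, -0.48, 7
            )
        )
        assert apply_model(profile, "D3").decision is Decision.DELETERIOUS

    def test_ddg_class_gate_by_config(self):
        from varsieve.consensus import ConsensusModelSpec

        spec = ConsensusModelSpec("D3", 4, True, True, stability_gate="ddg_class")
        profile = make_profile("sssss", conserved=True, destabilizing=True)
        profile = profile.with_evidence(
            stability=profile.stability.__class__(
                profile.stability.direction, -0.48, 7
            )
        )
        assert apply_model(profile, spec).decision is Decision.BENIGN


class TestOracleEquivalence:
    @pytest.mark.parametrize("policy", list(MissingPolicy))
    def test_all_243_call_states_all_models(self, policy):
        """The engine agrees with an independent brute-force counter on
        every per-tool call-state combination, model and policy."""
        for states in map("".join, itertools.product("snm", repeat=5)):
            for model_id in MODELS:
                for conserved, destab in [(True, True), (True, False),
                                          (False, True), (False, False)]:
                    profile = make_profile(
                        states, conserved=conserved, destabilizing=destab
                    )
                    got = apply_model(profile, model_id, policy).decision.value
                    want = oracle_decision(
                        states, model_id, policy.value, conserved, destab
                    )
                    assert got == want, (states, model_id, policy, conserved, destab)

    @pytest.mark.parametrize("policy", list(MissingPolicy))
    def test_x3_without_evidence_matches_oracle(self, policy):
        for states in ["sssss", "sssnm", "mmmmm"]:
            for model_id in ("A3", "B3", "C3", "D3"):
                got = apply_model(make_profile(states), model_id, policy)
                assert got.decision.value == oracle_decision(
                    states, model_id, policy.value, None, None
                )


def _deleterious_set(profiles, model_id, policy):
    return {
        i
        for i, p in enumerate(profiles)
        if apply_model(p, model_id, policy).decision is Decision.DELETERIOUS
    }


def _random_profiles(n, seed):
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        states = "".join(rng.choice(list("snm"), size=5, p=[0.4, 0.4, 0.2]))
        conserved = bool(rng.random() < 0.7)
        destabilizing = bool(rng.random() < 0.7)
        profiles.append(
            make_profile(states, rsid=f"rs{i}", conserved=conserved,
                         destabilizing=destabilizing)
        )
    return profiles


class TestNesting:
    @pytest.mark.parametrize("policy", list(MissingPolicy))
    def test_models_nest_on_fixture_and_random_profiles(self, policy):
        """A >= B >= C >= D (and A3 >= B3 >= C3 >= D3, X3 within X) as
        deleterious sets, for every missing-data policy."""
        fixture = variant_profiles()
        random = _random_profiles(1000, seed=20240917)
        for profiles in (fixture, random):
            sets = {m: _deleterious_set(profiles, m, policy) for m in MODELS}
            for hi, lo in [("A", "B"), ("B", "C"), ("C", "D"),
                           ("A3", "B3"), ("B3", "C3"), ("C3", "D3")]:
                assert sets[lo] <= sets[hi], (hi, lo, policy)
            for base in "ABCD":
                assert sets[base + "3"] <= sets[base], (base, policy)

    def test_permissive_effective_votes_dominate_strict(self):
        for states in map("".join, itertools.product("snm", repeat=5)):
            profile = make_profile(states)
            strict = count_votes(profile, MissingPolicy.STRICT)
            permissive = count_votes(profile, MissingPolicy.PERMISSIVE)
            assert permissive.effective_significant >= strict.effective_significant


class TestRankModels:
    def test_row_sums_fixed_at_class_sizes(self):
        profiles = _random_profiles(40, seed=7)
        truths = [TruthLabel.PATHOGENIC] * 18 + [TruthLabel.BENIGN] * 22
        counts = rank_models(profiles, truths)
        for c in counts.values():
            assert c.tp + c.fn == 18
            assert c.tn + c.fp == 22

    def test_all_benign_truth_has_no_positives(self):
        profiles = _random_profiles(10, seed=8)
        counts = rank_models(profiles, [TruthLabel.BENIGN] * 10)
        for c in counts.values():
            assert c.tp == 0 and c.fn == 0

    def test_unlabeled_profile_is_an_error(self):
        with pytest.raises(ValueError, match="unlabeled"):
            rank_models([make_profile("sssss")], ["pathogenic"])


class TestConsensusClassifier:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        from sklearn.exceptions import NotFittedError

        clf = ConsensusClassifier(model="C", missing_policy="permissive")
        assert clf.get_params() == {"model": "C", "missing_policy": "permissive"}
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        with pytest.raises(NotFittedError):
            clf.predict([make_profile("sssss")])

    def test_fit_predict_matches_apply_model(self):
        profiles = _random_profiles(50, seed=9)
        clf = ConsensusClassifier(model="D").fit(profiles)
        predicted = clf.predict(profiles)
        expected = [
            "deleterious"
            if apply_model(p, "D").decision is Decision.DELETERIOUS
            else "benign"
            for p in profiles
        ]
        assert list(predicted) == expected
        assert set(clf.classes_) == {"benign", "deleterious"}

    def test_score_accepts_truth_labels(self):
        profiles = [make_profile("sssss"), make_profile("nnnnn")]
        truths = [TruthLabel.PATHOGENIC, TruthLabel.BENIGN]
        clf = ConsensusClassifier(model="D").fit(profiles, truths)
        assert clf.score(profiles, truths) == 1.0

    def test_unknown_model_rejected_at_fit(self):
        with pytest.raises(ValueError, match="unknown model"):
            ConsensusClassifier(model="E").fit([make_profile("sssss")])
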