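"""Staged prioritization: stage gates, survivor nesting and traces."""

import pytest

from varsieve.cascade import (
    CascadeConfig,
    StageStatus,
    run_cascade,
    stage_conservation,
    stage_stability,
    stage_structure,
)
from varsieve.fixtures import SHORTLIST_RSIDS, candidate_profiles
from varsieve.types import (
    ConservationCall,
    StabilityCall,
    StabilityDirection,
    StructureCall,
)
from helpers import make_profile

CFG = CascadeConfig()


def profile_with(**evidence):
    return make_profile("sssss").with_evidence(**evidence)


class TestStageConservation:
    @pytest.mark.parametrize(
        "grade,status",
        [(8, StageStatus.PASS), (9, StageStatus.PASS), (7, StageStatus.PASS),
         (6, StageStatus.FAIL), (5, StageStatus.FAIL), (1, StageStatus.FAIL)],
    )
    def test_grade_gate(self, grade, status):
        p = profile_with(conservation=ConservationCall(grade))
        assert stage_conservation(p, CFG).status is status

    def test_absent_evidence_is_not_evaluated(self):
        assert (
            stage_conservation(make_profile("sssss"), CFG).status
            is StageStatus.NOT_EVALUATED
        )


class TestStageStability:
    @pytest.mark.parametrize(
        "direction,ddg,ri,status",
        [
            (StabilityDirection.DECREASE, -1.39, 9, StageStatus.PASS),
            (StabilityDirection.DECREASE, -0.48, 0, StageStatus.FAIL),  # RI 0
            (StabilityDirection.DECREASE, -1.50, 4, StageStatus.FAIL),  # RI 4
            (StabilityDirection.DECREASE, -1.00, 5, StageStatus.PASS),  # RI 5 passes
            (StabilityDirection.INCREASE, -1.00, 9, StageStatus.FAIL),
        ],
    )
    def test_direction_and_reliability_gate(self, direction, ddg, ri, status):
        p = profile_with(stability=StabilityCall(direction, ddg, ri))
        assert stage_stability(p, CFG).status is status


class TestStageStructure:
    @pytest.mark.parametrize(
        "tm,rmsd,status",
        [
            (0.934, 2.06, StageStatus.PASS),
            (0.262, 2.56, StageStatus.FAIL),  # low TM-score, good RMSD
            (0.6, 7.0, StageStatus.FAIL),  # RMSD bound
            (0.5, 2.0, StageStatus.FAIL),  # TM bound is exclusive
        ],
    )
    def test_fold_gate(self, tm, rmsd, status):
        p = profile_with(structure=StructureCall(tm, rmsd))
        assert stage_structure(p, CFG).status is status


class TestRunCascade:
    def test_published_candidates_reduce_8_to_6_to_3(self):
        """On the eight high-risk candidates with their published
        evidence, the stability gate leaves six, the structure gate
        three, and the shortlist is the published one."""
        res = run_cascade(candidate_profiles(), CascadeConfig(consensus_model=None))
        assert res.n_input == 8
        assert res.survivor_counts["conservation"] == 8
        assert res.survivor_counts["stability"] == 6
        assert res.survivor_counts["structure"] == 3
        assert set(res.shortlist) == set(SHORTLIST_RSIDS)

    def test_shortlist_annotations_attached(self):
        res = run_cascade(candidate_profiles(), CascadeConfig(consensus_model=None))
        annotated = {t.rsid: t for t in res.traces if t.shortlisted}
        assert set(annotated) == set(SHORTLIST_RSIDS)
        tyr = annotated["rs1126809"]
        assert "0.74" in tyr.mutpred_annotation
        assert "pathogenic" in tyr.mutpred_annotation
        assert "low confidence" in tyr.modpred_annotation

    def test_empty_input(self):
        res = run_cascade([], CascadeConfig())
        assert res.traces == [] and res.shortlist == []
        assert all(v == 0 for v in res.survivor_counts.values())

    def test_survivor_counts_nested(self):
        res = run_cascade(candidate_profiles(), CascadeConfig(consensus_model=None))
        counts = list(res.survivor_counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_fail_stops_later_stages(self):
        p = profile_with(
            conservation=ConservationCall(3),
            stability=StabilityCall(StabilityDirection.DECREASE, -1.0, 9),
            structure=StructureCall(0.9, 1.0),
        )
        res = run_cascade([p], CascadeConfig(consensus_model=None))
        trace = res.traces[0]
        assert trace.stages["conservation"].status is StageStatus.FAIL
        assert trace.stages["stability"].status is StageStatus.NOT_EVALUATED
        assert trace.stages["structure"].status is StageStatus.NOT_EVALUATED
        assert not trace.shortlisted

    def test_absent_evidence_distinct_from_fail(self):
        p = make_profile("sssss")  # consensus passes, no other evidence
        res = run_cascade([p], CascadeConfig())
        trace = res.traces[0]
        assert trace.stages["consensus"].status is StageStatus.PASS
        assert trace.stages["conservation"].status is StageStatus.NOT_EVALUATED
        assert trace.stages["conservation"].detail == "no conservation call"

    def test_reordering_profiles_never_changes_traces(self):
        profiles = candidate_profiles()
        forward = run_cascade(profiles, CascadeConfig(consensus_model=None))
        backward = run_cascade(profiles[::-1], CascadeConfig(consensus_model=None))
        by_rsid_f = {t.rsid: t.stages for t in forward.traces}
        by_rsid_b = {t.rsid: t.stages for t in backward.traces}
        for rsid in by_rsid_f:
            assert {k: v.status for k, v in by_rsid_f[rsid].items()} == {
                k: v.status for k, v in by_rsid_b[rsid].items()
            }
        assert set(forward.shortlist) == set(backward.shortlist)

    def test_consensus_stage_filters_low_vote_candidates(self):
        """With the consensus stage active, a 3-of-5 candidate stops at
        stage one even with perfect downstream evidence."""
        p = make_profile("sssnn").with_evidence(
            conservation=ConservationCall(9),
            stability=StabilityCall(StabilityDirection.DECREASE, -1.0, 9),
            structure=StructureCall(0.9, 1.0),
        )
        res = run_cascade([p], CascadeConfig(consensus_model="D"))
        assert res.traces[0].stages["consensus"].status is StageStatus.FAIL
        assert res.shortlist == []
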