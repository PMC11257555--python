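"""Subtyping: arm events, confidence gate, per-rule ground-truth recovery,
tie-breaks, and determinism."""

import dataclasses

import pytest

from pedcns.consensus_cnv import ConsensusCnvRegion
from pedcns.fixtures import ARM_TABLE, build_event_plans, plan_to_bundle, subtype_cohort
from pedcns.intervals import GenomicInterval
from pedcns.model import MethylPrediction, SpecimenRecord, Thresholds
from pedcns.subtypes import (
    call_arm_events,
    dispatch_histology,
    high_confidence,
    run_subtyping,
    subtype_mb_shh,
)

THR = Thresholds()
PLANS = build_event_plans()
BUNDLES = [plan_to_bundle(p, i) for i, p in enumerate(PLANS)]


def region(chrom, start, end, direction, sample="BS1"):
    return ConsensusCnvRegion(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, end),
        direction=direction,
        supporting_callers=frozenset({"controlfreec", "cnvkit"}),
    )


class TestArmEvents:
    def test_60_percent_coverage_calls_event(self):
        # chr9 p arm spans 4.5 Mb; 2.7 Mb of gain covers 60%
        regions = [region("chr9", 0, 2_700_000, "gain")]
        events = call_arm_events(regions, ARM_TABLE, THR)
        assert ("9p", "gain") in events["BS1"]

    def test_40_percent_coverage_is_no_event(self):
        regions = [region("chr9", 0, 1_800_000, "gain")]
        events = call_arm_events(regions, ARM_TABLE, THR)
        assert events["BS1"] == set()

    def test_no_regions_empty(self):
        assert call_arm_events([], ARM_TABLE, THR) == {}

    def test_overlapping_regions_not_double_counted(self):
        regions = [
            region("chr9", 0, 1_500_000, "gain"),
            region("chr9", 0, 1_500_000, "gain"),
        ]
        events = call_arm_events(regions, ARM_TABLE, THR)
        assert events["BS1"] == set()  # 1.5/4.5 even though summed bp would pass

    def test_unknown_chromosome_ignored(self):
        regions = [region("chrUn", 0, 3_000_000, "gain")]
        assert call_arm_events(regions, ARM_TABLE, THR)["BS1"] == set()


class TestConfidenceGate:
    @pytest.mark.parametrize("score,expected", [(0.8, True), (0.79, False)])
    def test_boundary(self, score, expected):
        pred = MethylPrediction("BS1", "dkfz_v12", "ATRT_MYC", score)
        assert high_confidence(pred, THR) is expected

    def test_absent_prediction_false(self):
        assert high_confidence(None, THR) is False


class TestGroundTruthRecovery:
    @pytest.mark.parametrize(
        "plan,bundle", list(zip(PLANS, BUNDLES)), ids=[p.event_id for p in PLANS]
    )
    def test_injected_lesion_recovers_expected_label(self, plan, bundle):
        result = run_subtyping([bundle])[0]
        assert result.molecular_subtype == plan.expected_subtype

    def test_cohort_order_independence(self):
        forward = run_subtyping(BUNDLES)
        backward = run_subtyping(list(reversed(BUNDLES)))
        by_event_f = {r.tumor_event_id: r.molecular_subtype for r in forward}
        by_event_b = {r.tumor_event_id: r.molecular_subtype for r in backward}
        assert by_event_f == by_event_b

    def test_every_covered_event_gets_exactly_one_label(self):
        results = run_subtyping(BUNDLES)
        for plan, result in zip(PLANS, results):
            if plan.expected_subtype is None:
                assert result.molecular_subtype is None
            else:
                assert isinstance(result.molecular_subtype, str)
                assert result.molecular_subtype


class TestMethylationPerturbation:
    def test_dropping_score_below_gate_flips_only_gated_rules(self):
        plans, bundles = subtype_cohort()
        baseline = run_subtyping(bundles)
        perturbed_bundles = []
        for bundle in bundles:
            preds = [
                dataclasses.replace(p, score=0.79) if p.score >= THR.methyl_confidence
                else p
                for p in bundle.methyl
            ]
            perturbed_bundles.append(dataclasses.replace(bundle, methyl=preds))
        perturbed = run_subtyping(perturbed_bundles)
        for plan, before, after in zip(plans, baseline, perturbed):
            if plan.methyl_gated:
                assert after.molecular_subtype != before.molecular_subtype, plan.event_id
            else:
                assert after.molecular_subtype == before.molecular_subtype, plan.event_id


class TestMbShhTieBreak:
    def _bundle(self, age, arms):
        specimen = SpecimenRecord(
            sample_id="BS1", participant_id="PT1", tumor_event_id="ev",
            pathology_diagnosis="Medulloblastoma", age_at_diagnosis_years=age,
        )
        import pedcns.subtypes.evidence as ev

        return ev.EvidenceBundle(
            specimen=specimen, arm_events=set(arms), rna_mb_label="SHH",
        )

    def test_2p_gain_under_five_prefers_gamma(self):
        # matches both beta (2p/2q gain) and gamma (2p gain); the more
        # specific single-criterion subgroup wins
        result = subtype_mb_shh(self._bundle(3.0, [("2p", "gain")]))
        assert result.molecular_subtype == "MB, SHH gamma"

    def test_2q_gain_is_beta_only(self):
        result = subtype_mb_shh(self._bundle(3.0, [("2q", "gain")]))
        assert result.molecular_subtype == "MB, SHH beta"

    def test_no_lesion_stays_unrefined_shh(self):
        result = subtype_mb_shh(self._bundle(7.0, []))
        assert result.molecular_subtype == "MB, SHH"


class TestDispatch:
    @pytest.mark.parametrize(
        "diagnosis,expected",
        [
            ("High-grade glioma/astrocytoma", "hgg"),
            ("Medulloblastoma", "mb"),
            ("Ependymoma", "epn"),
            ("Ganglioneuroblastoma", "nbl"),
            ("Meningioma", None),
        ],
    )
    def test_keyword_dispatch(self, diagnosis, expected):
        assert dispatch_histology(diagnosis) == expected
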