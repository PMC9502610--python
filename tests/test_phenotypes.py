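import datetime

import numpy as np
import pytest

from ckdphen.model import CodeSystem, CodedEntry
from ckdphen.phenotypes import (
    AlgorithmConfig,
    CkdDefinition,
    CkdStage,
    Evidence,
    RrtModality,
    at_risk_ckd,
    classify_ckd,
    classify_cvd,
    classify_hypertension,
    classify_patient,
    classify_rrt,
    classify_t2dm,
)

from conftest import AS_OF, day, make_record
from oracles import oracle_classify_ckd, random_small_record


class TestRrt:
    def test_single_transplant_code_dominates(self, algo_config):
        rec = make_record(icd_codes=[(400, "Z94.0"), (20, "Z49.1")])
        res = classify_rrt(rec, algo_config)
        assert res.rrt and res.modality is RrtModality.TRANSPLANT

    def test_recent_dense_dialysis_is_maintenance(self, algo_config):
        rec = make_record(icd_codes=[(d, "Z49.1") for d in (5, 12, 19, 26, 30)])
        res = classify_rrt(rec, algo_config)
        assert res.rrt and res.modality is RrtModality.HAEMODIALYSIS

    def test_historic_single_dialysis_is_unspecified(self, algo_config):
        """Episodic dialysis years ago: RRT-positive, but no maintenance label."""
        rec = make_record(icd_codes=[(730, "Z49.1")])
        res = classify_rrt(rec, algo_config)
        assert res.rrt and res.modality is RrtModality.UNSPECIFIED

    def test_event_count_by_recency_grid(self, algo_config):
        """Maintenance label iff >= 3 events fall inside the 90-day window."""
        for n_recent in range(0, 5):
            for n_old in range(0, 3):
                offsets = [10 + 7 * i for i in range(n_recent)] + \
                          [200 + 30 * i for i in range(n_old)]
                if not offsets:
                    continue
                rec = make_record(icd_codes=[(d, "Z49.2") for d in offsets])
                res = classify_rrt(rec, algo_config)
                assert res.rrt
                expected = (RrtModality.PERITONEAL_DIALYSIS if n_recent >= 3
                            else RrtModality.UNSPECIFIED)
                assert res.modality is expected, (n_recent, n_old)

    def test_no_rrt_codes(self, algo_config):
        res = classify_rrt(make_record(), algo_config)
        assert not res.rrt and res.modality is RrtModality.NONE


class TestClassifyCkd:
    def test_g2_with_single_elevated_uacr_is_no_disease(self, algo_config):
        """One elevated uACR plus one eGFR 60-89 does not meet persistence."""
        rec = make_record(uacrs=[(30, 5.0)], egfr_reported=[(30, 75.0)])
        res = classify_ckd(rec, algo_config)
        assert not res.pooled_positive and res.stage is CkdStage.NONE

    def test_chronic_low_egfr_stages_3a(self, algo_config):
        rec = make_record(egfr_reported=[(120, 50.0), (0, 48.0)])
        res = classify_ckd(rec, algo_config)
        assert res.stage is CkdStage.CKD3A
        assert res.basis == frozenset({Evidence.EGFR_CRITERIA})

    def test_code_only_ckd_is_pooled_positive_unstaged(self, algo_config):
        rec = make_record(icd_codes=[(100, "N18.9")])
        res = classify_ckd(rec, algo_config)
        assert res.pooled_positive and res.stage is CkdStage.NONE
        assert res.basis == frozenset({Evidence.CKD_RELATED_CODES})

    def test_code_implied_stage_when_no_labs(self, algo_config):
        rec = make_record(icd_codes=[(100, "N18.3")])
        res = classify_ckd(rec, algo_config)
        assert res.stage is CkdStage.CKD3A
        assert Evidence.CODE_IMPLIED_STAGE in res.basis

    def test_lab_staging_beats_code_implied_stage(self, algo_config):
        rec = make_record(egfr_reported=[(120, 20.0), (0, 22.0)],
                          icd_codes=[(100, "N18.3")])
        assert classify_ckd(rec, algo_config).stage is CkdStage.CKD4

    def test_definition_variants_on_borderline_albuminuria(self, algo_config):
        """Two elevated uACR 30 days apart with eGFR 75-78: stage 2 under the
        default definition, negative under both sensitivity-analysis variants."""
        rec = make_record(uacrs=[(30, 5.0), (0, 6.0)],
                          egfr_reported=[(40, 75.0), (0, 78.0)])
        default = classify_ckd(rec, algo_config)
        assert default.stage is CkdStage.CKD2
        stringent = classify_ckd(
            rec, algo_config.with_definition(CkdDefinition.STRINGENT_UACR))
        assert not stringent.pooled_positive
        stage3a = classify_ckd(
            rec, algo_config.with_definition(CkdDefinition.STAGE3A_PLUS))
        assert not stage3a.pooled_positive

    def test_albuminuria_with_preserved_egfr_is_stage1(self, algo_config):
        rec = make_record(uacrs=[(120, 5.0), (0, 6.0)],
                          egfr_reported=[(0, 95.0)])
        assert classify_ckd(rec, algo_config).stage is CkdStage.CKD1

    def test_rrt_suppresses_numeric_stage(self, algo_config):
        rec = make_record(egfr_reported=[(120, 10.0), (0, 9.0)],
                          icd_codes=[(5, "Z49.1"), (12, "Z49.1"), (19, "Z49.1")])
        res = classify_ckd(rec, algo_config)
        assert res.stage is CkdStage.RRT and res.rrt_modality is RrtModality.HAEMODIALYSIS

    def test_determinism(self, algo_config):
        rec = make_record(uacrs=[(120, 5.0), (0, 6.0)], egfr_reported=[(0, 95.0)])
        assert classify_ckd(rec, algo_config) == classify_ckd(rec, algo_config)

    def test_matches_rule_disjunction_oracle_on_random_records(self, algo_config):
        rng = np.random.default_rng(42)
        for i in range(2000):
            rec = random_small_record(rng, f"R{i}", AS_OF)
            for variant in CkdDefinition:
                got = classify_ckd(rec, algo_config.with_definition(variant))
                want_pos, want_stage = oracle_classify_ckd(rec, AS_OF, variant.value)
                assert (got.pooled_positive, got.stage) == (want_pos, want_stage), \
                    (i, variant, rec)

    def test_code_arm_monotonicity(self, algo_config):
        """Adding a CKD-related code never flips a positive to negative."""
        rng = np.random.default_rng(7)
        extra = CodedEntry("X", CodeSystem.ICD10AM, "N18.9", day(50))
        for i in range(300):
            rec = random_small_record(rng, "X", AS_OF)
            before = classify_ckd(rec, algo_config)
            rec2 = type(rec)(
                demographics=rec.demographics, labs=rec.labs,
                observations=rec.observations, codes=rec.codes + (extra,),
                medications=rec.medications, procedures=rec.procedures)
            after = classify_ckd(rec2, algo_config)
            if before.pooled_positive:
                assert after.pooled_positive


class TestComorbidClassifiers:
    def test_two_elevated_hba1c_is_diabetes(self, algo_config):
        rec = make_record(hba1cs=[(200, 60.0), (0, 62.0)])
        res = classify_t2dm(rec, algo_config)
        assert res.positive and res.basis == frozenset({Evidence.LABS})

    def test_single_historic_elevated_hba1c_is_not_diabetes(self, algo_config):
        """One elevated reading among normals, no medication, no code."""
        rec = make_record(hba1cs=[(900, 60.0), (400, 40.0), (200, 41.0), (0, 39.0)])
        assert not classify_t2dm(rec, algo_config).positive

    def test_glucose_lowering_medication_arm(self, algo_config):
        rec = make_record(medications=[(100, "A10BA02")])
        res = classify_t2dm(rec, algo_config)
        assert res.positive and res.basis == frozenset({Evidence.MEDICATIONS})

    def test_two_elevated_bp_on_distinct_dates_is_hypertension(self, algo_config):
        rec = make_record(bps=[(60, 150.0, 80.0), (0, 145.0, 85.0)])
        res = classify_hypertension(rec, algo_config)
        assert res.positive and res.basis == frozenset({Evidence.OBSERVATIONS})

    def test_single_elevated_bp_is_not_hypertension(self, algo_config):
        assert not classify_hypertension(
            make_record(bps=[(0, 160.0, 100.0)]), algo_config).positive

    def test_bp_rule_enumeration(self, algo_config):
        """The observation arm fires iff >= 2 distinct dates are elevated."""
        readings = [(90, 150.0, 70.0), (60, 120.0, 95.0),
                    (30, 118.0, 72.0), (0, 141.0, 60.0)]
        import itertools
        for r in range(0, 5):
            for subset in itertools.combinations(readings, r):
                rec = make_record(bps=list(subset))
                elevated_dates = {d for d, s, dia in subset if s >= 140 or dia >= 90}
                assert classify_hypertension(rec, algo_config).positive == \
                    (len(elevated_dates) >= 2), subset

    def test_hypertension_code_arm(self, algo_config):
        res = classify_hypertension(make_record(icd_codes=[(10, "I10")]), algo_config)
        assert res.positive and res.basis == frozenset({Evidence.CODES})

    def test_cvd_is_code_only(self, algo_config):
        assert classify_cvd(make_record(icd_codes=[(10, "I21.4")]), algo_config).positive
        # cardiovascular medications alone never make CVD positive
        assert not classify_cvd(
            make_record(medications=[(10, "C07AB02"), (5, "C10AA01")]),
            algo_config).positive
        assert not classify_cvd(make_record(), algo_config).positive


class TestAtRisk:
    def test_diabetes_implies_at_risk(self, algo_config):
        rec = make_record(hba1cs=[(200, 60.0), (0, 62.0)])
        assert at_risk_ckd(rec, algo_config)

    def test_external_risk_score_strict_inequality(self, algo_config):
        empty = make_record()
        assert at_risk_ckd(empty, algo_config, external_cvd_risk=16.0)
        assert not at_risk_ckd(empty, algo_config, external_cvd_risk=15.0)

    def test_empty_record_not_at_risk(self, algo_config):
        assert not at_risk_ckd(make_record(), algo_config)

    def test_aki_history_is_at_risk(self, algo_config):
        assert at_risk_ckd(make_record(icd_codes=[(500, "N17.1")]), algo_config)
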