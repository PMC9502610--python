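import math
import warnings

import numpy as np
import pytest

from ckdphen.config import config_from_mapping, _default_raw
from ckdphen.phenotypes import AlgorithmConfig, CkdStage, classify_patient
from ckdphen.validation import (
    ConfusionCounts,
    SampleSizeSpec,
    accuracy_report,
    buderer_sample_size,
    coded_stage_classifier,
    cohens_kappa,
    confusion,
    one_vs_rest,
    stage_confusion_matrix,
    stratified_sample,
    subgroup_assign,
)

from conftest import AS_OF, make_record


class TestConfusion:
    def test_identity_labels(self):
        gold = {f"p{i}": i < 6 for i in range(10)}
        c = confusion(gold, gold)
        assert (c.tp, c.tn, c.fp, c.fn) == (6, 4, 0, 0)

    def test_all_positive_gold_all_negative_pred(self):
        gold = {f"p{i}": True for i in range(7)}
        pred = {f"p{i}": False for i in range(7)}
        assert confusion(gold, pred).fn == 7

    def test_random_labelling_matches_sklearn(self):
        from sklearn.metrics import confusion_matrix

        rng = np.random.default_rng(3)
        gold = {f"p{i}": bool(rng.integers(2)) for i in range(20)}
        pred = {f"p{i}": bool(rng.integers(2)) for i in range(20)}
        c = confusion(gold, pred)
        ids = sorted(gold)
        tn, fp, fn, tp = confusion_matrix(
            [gold[i] for i in ids], [pred[i] for i in ids], labels=[False, True]).ravel()
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_mismatched_patient_sets_hard_error(self):
        with pytest.raises(ValueError, match="p2"):
            confusion({"p1": True}, {"p2": True})


class TestAccuracyReport:
    def test_wald_interval_hand_calculation(self):
        rep = accuracy_report(ConfusionCounts(tp=130, fp=0, fn=10, tn=1))
        se = rep.sensitivity
        assert se.value == pytest.approx(0.9286, abs=5e-4)
        assert se.ci_low == pytest.approx(0.886, abs=1e-3)
        assert se.ci_high == pytest.approx(0.971, abs=1e-3)

    def test_zero_width_interval_at_perfect_sensitivity(self):
        """The asymptotic interval collapses to (1, 1) at 100%."""
        rep = accuracy_report(ConfusionCounts(tp=50, fp=0, fn=0, tn=5))
        se = rep.sensitivity
        assert (se.value, se.ci_low, se.ci_high) == (1.0, 1.0, 1.0)

    def test_auc_is_balanced_accuracy(self):
        rep = accuracy_report(ConfusionCounts(tp=93, fn=7, tn=73, fp=27))
        assert rep.auc == pytest.approx((0.93 + 0.73) / 2)

    def test_zero_denominator_flagged_undefined(self):
        rep = accuracy_report(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert not rep.sensitivity.defined
        assert rep.specificity.defined
        assert rep.auc is None

    def test_ci_width_shrinks_as_inverse_sqrt_n(self):
        widths = []
        for n in (50, 200, 800):
            c = ConfusionCounts(tp=int(0.9 * n), fn=n - int(0.9 * n), fp=0, tn=1)
            se = accuracy_report(c).sensitivity
            widths.append(se.ci_high - se.ci_low)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.05)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.05)


class TestBuderer:
    def test_reported_study_size(self):
        res = buderer_sample_size(SampleSizeSpec(
            sensitivity=0.95, specificity=0.90, prevalence=0.50))
        assert res.n_required == 277

    def test_sensitivity_component_hand_calculation(self):
        res = buderer_sample_size(SampleSizeSpec(
            sensitivity=0.95, specificity=0.90, prevalence=0.50))
        assert res.n_sensitivity == 146  # ceil(1.96^2*0.95*0.05/0.0025/0.5)

    def test_half_maximises_component_size(self):
        at_half = buderer_sample_size(SampleSizeSpec(0.5, 0.9, 0.5)).n_sensitivity
        for se in (0.1, 0.3, 0.7, 0.9, 0.99):
            assert buderer_sample_size(SampleSizeSpec(se, 0.9, 0.5)).n_sensitivity \
                <= at_half

    def test_symmetry_under_se_sp_and_prevalence_swap(self):
        a = buderer_sample_size(SampleSizeSpec(0.95, 0.80, 0.3))
        b = buderer_sample_size(SampleSizeSpec(0.80, 0.95, 0.7))
        assert (a.n_sensitivity, a.n_specificity) == (b.n_specificity, b.n_sensitivity)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(0.95, 0.9, 1.0)


class TestKappa:
    def test_perfect_concordance(self):
        po, kappa = cohens_kappa([[30, 0], [0, 20]])
        assert (po, kappa) == (1.0, 1.0)

    def test_hand_calculated_two_by_two(self):
        po, kappa = cohens_kappa([[40, 10], [5, 45]])
        assert po == pytest.approx(0.85)
        assert kappa == pytest.approx(0.70)

    def test_matches_sklearn_on_simulated_raters(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, size=500)
        b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 3, size=500))
        table = np.zeros((3, 3))
        for x, y in zip(a, b):
            table[x, y] += 1
        _, kappa = cohens_kappa(table)
        assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_raters_give_near_zero_kappa(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, size=10_000)
        b = rng.integers(0, 2, size=10_000)
        table = np.zeros((2, 2))
        for x, y in zip(a, b):
            table[x, y] += 1
        _, kappa = cohens_kappa(table)
        assert abs(kappa) < 0.03

    def test_kappa_one_iff_off_diagonal_zero(self):
        _, kappa = cohens_kappa([[30, 1], [0, 20]])
        assert kappa < 1.0

    def test_empty_table_hard_error(self):
        with pytest.raises(ValueError):
            cohens_kappa([[0, 0], [0, 0]])


class TestStageMatrix:
    def test_identical_maps_give_diagonal(self):
        stages = {f"p{i}": s for i, s in enumerate(CkdStage)}
        mat = stage_confusion_matrix(stages, stages)
        assert mat.values.sum() == np.trace(mat.values) == len(CkdStage)

    def test_one_vs_rest_consistent_with_accuracy_report(self):
        rng = np.random.default_rng(9)
        levels = list(CkdStage)
        gold = {f"p{i}": levels[rng.integers(len(levels))] for i in range(30)}
        pred = {f"p{i}": levels[rng.integers(len(levels))] for i in range(30)}
        mat = stage_confusion_matrix(gold, pred)
        for stage in CkdStage:
            c = one_vs_rest(mat, stage)
            g = {p: s is stage for p, s in gold.items()}
            q = {p: s is stage for p, s in pred.items()}
            assert c == confusion(g, q)

    def test_random_stages_match_brute_tally(self):
        rng = np.random.default_rng(13)
        levels = list(CkdStage)
        gold = {f"p{i}": levels[rng.integers(len(levels))] for i in range(30)}
        pred = {f"p{i}": levels[rng.integers(len(levels))] for i in range(30)}
        mat = stage_confusion_matrix(gold, pred)
        for g in levels:
            for p in levels:
                want = sum(1 for pid in gold if gold[pid] is g and pred[pid] is p)
                assert mat.loc[g.value, p.value] == want


class TestSubgroups:
    def _labels(self, rec, algo_config):
        return classify_patient(rec, algo_config)

    def test_ckd3a_patient_lands_in_subgroup_2(self, algo_config):
        rec = make_record(egfr_reported=[(400, 50.0), (100, 52.0), (0, 48.0)])
        assert subgroup_assign(rec, self._labels(rec, algo_config), algo_config) == 2

    def test_rrt_patient_lands_in_subgroup_4(self, algo_config):
        rec = make_record(
            egfr_reported=[(400, 9.0), (100, 8.0), (0, 8.0)],
            icd_codes=[(5, "Z49.1"), (12, "Z49.1"), (19, "Z49.1")])
        assert subgroup_assign(rec, self._labels(rec, algo_config), algo_config) == 4

    def test_under_three_entries_is_ineligible(self, algo_config):
        rec = make_record(egfr_reported=[(100, 50.0), (0, 48.0)])
        assert subgroup_assign(rec, self._labels(rec, algo_config), algo_config) \
            == "ineligible"

    def test_at_risk_without_ckd_is_subgroup_1(self, algo_config):
        rec = make_record(hba1cs=[(300, 60.0), (0, 62.0)],
                          egfr_reported=[(0, 95.0)])
        assert subgroup_assign(rec, self._labels(rec, algo_config), algo_config) == 1

    def test_partition_over_synthetic_cohort(self, algo_config, perfect_cohort):
        """Every eligible patient lands in exactly one subgroup (priorities
        make the six criteria disjoint)."""
        cohort, truths = perfect_cohort
        for pid, rec in cohort.items():
            g = subgroup_assign(rec, classify_patient(rec, algo_config), algo_config)
            assert g == truths[pid].subgroup


class TestStratifiedSample:
    def test_reproducible_under_seed(self):
        groups = {1: [f"a{i}" for i in range(100)], 2: [f"b{i}" for i in range(80)]}
        assert stratified_sample(groups, 60, seed=42) == \
            stratified_sample(groups, 60, seed=42)

    def test_small_subgroup_returned_whole_with_warning(self):
        groups = {1: [f"a{i}" for i in range(40)]}
        with pytest.warns(UserWarning, match="only 40"):
            out = stratified_sample(groups, 60, seed=1)
        assert len(out[1]) == 40

    def test_samples_are_subsets_of_requested_size(self):
        groups = {g: [f"g{g}p{i}" for i in range(1000)] for g in range(1, 7)}
        out = stratified_sample(groups, 60, seed=0)
        for g, ids in out.items():
            assert len(ids) == 60 and len(set(ids)) == 60
            assert set(ids) <= set(groups[g])


@pytest.fixture(scope="module")
def icpc_staging_config():
    """Config whose ICPC map carries stage information, so the
    two-system averaging rule can activate."""
    raw = _default_raw()
    raw["stage_codes"]["ICPC2"] = {"U28": "CKD3a", "U29": "CKD4"}
    raw["codesets"]["ckd_related"]["ICPC2"] = ["U99", "U28", "U29"]
    app = config_from_mapping(raw)
    return AlgorithmConfig(as_of=AS_OF, app=app)


class TestCodedStageComparator:
    def test_disagreeing_systems_average_rounds_up(self, icpc_staging_config):
        """ICD stage 3 vs ICPC stage 4 -> ceil(3.5) = stage 4."""
        rec = make_record(icd_codes=[(100, "N18.3")], icpc_codes=[(50, "U29")])
        assert coded_stage_classifier(rec, icpc_staging_config) is CkdStage.CKD4

    def test_single_system_passthrough(self, algo_config):
        rec = make_record(icd_codes=[(100, "N18.5")])
        assert coded_stage_classifier(rec, algo_config) is CkdStage.CKD5

    def test_rrt_codes_dominate(self, algo_config):
        rec = make_record(icd_codes=[(100, "N18.5"), (10, "Z49.1")])
        assert coded_stage_classifier(rec, algo_config) is CkdStage.RRT

    def test_no_renal_codes_is_none(self, algo_config):
        assert coded_stage_classifier(make_record(), algo_config) is CkdStage.NONE
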