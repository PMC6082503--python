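"""Classification, confusion metrics, threshold selection, BCa bootstrap
intervals and Table-1-style cohort comparisons."""

import numpy as np
import pytest
from scipy import stats

from cadnet.evaluation import (
    CategoricalCounts,
    ConfusionMatrix,
    ContinuousSummary,
    DegenerateBootstrapError,
    auc_metric,
    bootstrap_ci,
    chi2_from_counts,
    classify,
    compare_demographics,
    confusion_and_metrics,
    select_threshold,
    sensitivity_metric,
    specificity_metric,
    ttest_from_summary,
)


class TestClassify:
    def test_below_threshold_negative_at_threshold_positive(self):
        pred = classify(np.array([1.0, 2.0, 3.0]), threshold=2.0)
        assert list(pred) == [False, True, True]

    def test_threshold_below_min_all_positive(self):
        assert classify(np.array([1.0, 2.0]), threshold=0.0).all()

    def test_threshold_above_max_all_negative(self):
        assert not classify(np.array([1.0, 2.0]), threshold=5.0).any()


class TestConfusionMetrics:
    def test_standard_formulas(self):
        labels = np.array([1] * 25 + [0] * 45, bool)
        pred = labels.copy()
        pred[:2] = False   # 2 FN -> sens 23/25
        pred[25:27] = True  # 2 FP
        cm, m = confusion_and_metrics(pred, labels)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (23, 2, 2, 43)
        assert cm.total == 70
        assert m["sensitivity"] == pytest.approx(0.92)
        assert m["specificity"] == pytest.approx(43 / 45)
        assert m["npv"] == pytest.approx(43 / 45)
        assert m["ppv"] == pytest.approx(23 / 25)

    def test_undefined_ratio_reported_absent(self):
        labels = np.zeros(10, bool)
        pred = np.zeros(10, bool)
        _, m = confusion_and_metrics(pred, labels)
        assert m["sensitivity"] is None  # no positives: not coerced to 0
        assert m["ppv"] is None
        assert m["specificity"] == 1.0

    def test_cells_sum_to_n(self, rng):
        pred = rng.random(50) < 0.5
        labels = rng.random(50) < 0.3
        cm, _ = confusion_and_metrics(pred, labels)
        assert cm.total == 50


class TestSelectThreshold:
    def test_enumerated_operating_points(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1], bool)
        t, info = select_threshold(scores, labels, sens_floor=0.9)
        assert 0.2 < t <= 0.8
        assert info["sensitivity"] == 1.0 and info["specificity"] == 1.0
        assert not info["warning"]

    def test_perfect_separation_any_gap_threshold(self, rng):
        scores = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 10)])
        labels = np.concatenate([np.zeros(20, bool), np.ones(10, bool)])
        t, info = select_threshold(scores, labels)
        assert info["sensitivity"] == 1.0 and info["specificity"] == 1.0

    def test_floor_zero_excludes_all_negative_classifier(self):
        # sens tie-break: among max-specificity points, prefer sensitivity > 0
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1], bool)
        t, info = select_threshold(scores, labels, sens_floor=0.0)
        assert info["sensitivity"] == 1.0 and info["specificity"] == 1.0

    def test_unreachable_floor_falls_back_with_warning(self):
        # sensitivity 1 is always reachable (call everyone positive), so
        # only a floor above 1 exercises the fallback contract
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([0, 0, 1, 1], bool)
        t, info = select_threshold(scores, labels, sens_floor=1.01)
        assert info["warning"]
        assert info["sensitivity"] == 1.0  # maximal-sensitivity point

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([1.0, 2.0]), np.array([1, 1], bool))


class TestBootstrapCI:
    def _cohort(self, n_fn=2):
        labels = np.array([1] * 25 + [0] * 25, bool)
        pred = labels.copy()
        pred[:n_fn] = False
        return pred, labels

    def test_zero_variance_statistic_collapses(self):
        pred, labels = self._cohort(n_fn=0)
        lo, hi = bootstrap_ci(sensitivity_metric, pred, labels, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_per_seed(self):
        pred, labels = self._cohort()
        a = bootstrap_ci(sensitivity_metric, pred, labels, seed=7)
        b = bootstrap_ci(sensitivity_metric, pred, labels, seed=7)
        assert a == b
        c = bootstrap_ci(sensitivity_metric, pred, labels, seed=8)
        assert a != c

    def test_brackets_point_and_binomial_width(self):
        """At TP+FN = 25 and point 0.92, the BCa width must be within 30% of
        the Clopper-Pearson exact binomial width."""
        pred, labels = self._cohort(n_fn=2)  # sens 23/25 = 0.92
        lo, hi = bootstrap_ci(sensitivity_metric, pred, labels, n_boot=2000, seed=1)
        assert lo <= 0.92 <= hi
        assert 0.0 <= lo <= hi <= 1.0
        cp_lo = stats.beta.ppf(0.025, 23, 3)
        cp_hi = stats.beta.ppf(0.975, 24, 2)
        assert (hi - lo) == pytest.approx(cp_hi - cp_lo, rel=0.30)

    def test_matches_scipy_bca_on_continuous_statistic(self, rng):
        scores = rng.standard_normal(60)
        labels = rng.random(60) < 0.4

        def stat(idx_scores, idx_labels):
            return auc_metric(idx_scores, idx_labels)

        lo, hi = bootstrap_ci(stat, scores, labels, n_boot=4000, seed=3)
        ref = stats.bootstrap(
            (np.arange(60),),
            lambda idx: auc_metric(scores[idx.astype(int)], labels[idx.astype(int)]),
            n_resamples=4000, method="BCa", vectorized=False,
            random_state=np.random.default_rng(3),
        )
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.03)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.03)

    def test_empirical_coverage_near_nominal(self):
        """~95% of BCa intervals should contain the true sensitivity (0.80,
        25 positives) across simulated replicates."""
        labels = np.array([1] * 25 + [0] * 25, bool)
        rng = np.random.default_rng(0)
        covered = 0
        n_rep = 200
        for r in range(n_rep):
            pred = labels.copy()
            pred[:25] = rng.random(25) < 0.80
            lo, hi = bootstrap_ci(sensitivity_metric, pred, labels, n_boot=600, seed=r)
            covered += lo <= 0.80 <= hi
        assert 0.90 <= covered / n_rep <= 0.99

    def test_mostly_degenerate_resamples_error(self):
        labels = np.zeros(12, bool)
        labels[0] = True
        pred = labels.copy()

        def exactly_one_positive(p, l):
            # defined on the full sample, undefined on ~62% of resamples
            return 1.0 if l.sum() == 1 else np.nan

        with pytest.raises(DegenerateBootstrapError):
            bootstrap_ci(exactly_one_positive, pred, labels, n_boot=200, seed=0)


class TestDemographicsComparison:
    def test_printed_age_row_reproduces(self):
        """Development 61.5 +/- 10.7 (n=512) vs verification 59.0 +/- 9.8
        (n=94): the pooled-variance t-test p-value rounds to 0.04."""
        t, df, p = ttest_from_summary(
            ContinuousSummary(61.5, 10.7, 512), ContinuousSummary(59.0, 9.8, 94)
        )
        assert df == 604
        assert round(p, 2) == 0.04

    def test_matches_scipy_pooled_ttest(self):
        t, df, p = ttest_from_summary(
            ContinuousSummary(61.5, 10.7, 512), ContinuousSummary(59.0, 9.8, 94)
        )
        res = stats.ttest_ind_from_stats(61.5, 10.7, 512, 59.0, 9.8, 94, equal_var=True)
        assert t == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_identical_groups_p_one(self):
        a = ContinuousSummary(10.0, 2.0, 50)
        _, _, p = ttest_from_summary(a, a)
        assert p == 1.0

    def test_large_separation_tiny_p(self):
        _, _, p = ttest_from_summary(
            ContinuousSummary(0.0, 1.0, 1000), ContinuousSummary(1.0, 1.0, 1000)
        )
        assert p < 1e-10

    def test_chi_square_on_counts(self):
        chi2, p = chi2_from_counts(CategoricalCounts(308, 512), CategoricalCounts(65, 94))
        ref_chi2, ref_p, _, _ = stats.chi2_contingency(
            [[308, 204], [65, 29]], correction=False
        )
        assert chi2 == pytest.approx(ref_chi2)
        assert p == pytest.approx(ref_p)

    def test_table_structure_and_rounding(self, rng):
        a = {"age": rng.normal(60, 10, 200), "male": rng.random(200) < 0.6}
        b = {"age": rng.normal(60, 10, 100), "male": rng.random(100) < 0.6}
        table = compare_demographics(a, b)
        assert list(table["variable"]) == ["age", "male"]
        assert set(table["test"]) == {"pooled t", "chi-square"}
        assert all(table["p_display"] == table["p_value"].round(2))


def test_confusion_matrix_from_predictions_validates_lengths():
    with pytest.raises(ValueError):
        ConfusionMatrix.from_predictions(np.zeros(3, bool), np.zeros(4, bool))
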