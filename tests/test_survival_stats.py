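import numpy as np
import pytest
from scipy import stats as sps

from omisurv import (
    assoc_stats,
    chi2_independence,
    coxph_univariate,
    km_estimate,
    km_median,
    logrank_test,
    roc_auc,
)
from omisurv.survival_stats import compare_survival


def _cohort(seed=0, n=80, beta=0.7, binary=False):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float) if binary else rng.standard_normal(n)
    t = rng.exponential(100 * np.exp(-beta * x))
    e = (rng.random(n) < 0.8).astype(int)
    return x, t, e


class TestKaplanMeier:
    def test_hand_computed_product_limit(self, clinical_10):
        t = clinical_10.data["time_days"].to_numpy()
        e = clinical_10.data["event"].to_numpy()
        grid, surv = km_estimate(t, e)
        np.testing.assert_array_equal(grid, [0, 5, 8, 12, 20, 30])
        np.testing.assert_allclose(
            surv, [1, 9 / 10, 4 / 5, 24 / 35, 96 / 175, 64 / 175], rtol=0, atol=1e-15
        )

    def test_all_censored_flat_at_one(self):
        grid, surv = km_estimate([3.0, 7.0, 9.0], [0, 0, 0])
        np.testing.assert_array_equal(surv, [1.0])

    def test_single_event_of_four(self):
        grid, surv = km_estimate([10.0, 12.0, 15.0, 20.0], [1, 0, 0, 0])
        assert surv[-1] == 0.75

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        _, t, e = _cohort(seed=3, n=60)
        grid, surv = km_estimate(t, e)
        km = lifelines.KaplanMeierFitter().fit(t, e)
        ref = km.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(surv, ref, atol=1e-12)

    def test_no_censoring_complements_ecdf(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(50, 40)
        grid, surv = km_estimate(t, np.ones(40, dtype=int))
        ecdf = np.array([(t <= g).mean() for g in grid])
        np.testing.assert_allclose(surv, 1 - ecdf, atol=1e-12)

    def test_median(self):
        assert km_median([10.0, 20.0, 30.0, 40.0], [1, 1, 1, 1]) == 20.0
        assert km_median([10.0, 20.0], [0, 0]) == np.inf

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([5.0, 10.0, 15.0, 20.0])
        e = np.array([1, 1, 0, 1])
        chi2, p = logrank_test([t, t], [e, e])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_groups_two_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        ts = [rng.exponential(50, 20) for _ in range(3)]
        es = [np.ones(20, dtype=int) for _ in range(3)]
        chi2, p = logrank_test(ts, es)
        assert p == pytest.approx(float(sps.chi2.sf(chi2, df=2)))

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(4)
        t = rng.exponential(50, 90)
        e = (rng.random(90) < 0.7).astype(int)
        g = rng.integers(0, 3, 90)
        chi2, p = logrank_test(
            [t[g == k] for k in range(3)], [e[g == k] for k in range(3)]
        )
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_to_monotone_time_transform(self):
        x, t, e = _cohort(seed=6, n=60, binary=True)
        groups = [t[x == 0], t[x == 1]]
        events = [e[x == 0], e[x == 1]]
        chi2_a, _ = logrank_test(groups, events)
        chi2_b, _ = logrank_test([np.log1p(g) for g in groups], events)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([[1.0, 2.0], []], [[1, 1], []])


class TestCoxUnivariate:
    def test_score_test_equals_logrank_for_binary_covariate(self):
        x, t, e = _cohort(seed=0, n=60, binary=True)
        assoc = coxph_univariate(x, t, e)
        chi2, p = logrank_test([t[x == 0], t[x == 1]], [e[x == 0], e[x == 1]])
        assert assoc.chi2 == pytest.approx(chi2, abs=1e-6)
        assert assoc.p_value == pytest.approx(p, abs=1e-6)

    def test_coefficient_matches_scikit_survival_breslow(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        x, t, e = _cohort(seed=5, n=80)
        assoc = coxph_univariate(x, t, e)
        y = np.array(
            [(bool(ei), ti) for ei, ti in zip(e, t)], dtype=[("e", bool), ("t", float)]
        )
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(x.reshape(-1, 1), y)
        assert assoc.coef == pytest.approx(float(ref.coef_[0]), abs=1e-6)

    def test_sign_flip_symmetry(self):
        x, t, e = _cohort(seed=8)
        a = coxph_univariate(x, t, e)
        b = coxph_univariate(-x, t, e)
        assert b.coef == pytest.approx(-a.coef, abs=1e-8)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-9)

    def test_identical_feature_identical_result(self):
        x, t, e = _cohort(seed=9)
        a = coxph_univariate(x, t, e)
        b = coxph_univariate(x.copy(), t, e)
        assert (a.coef, a.p_value) == (b.coef, b.p_value)

    def test_null_type_one_error_calibrated(self):
        # feature independent of survival: rejection rate at alpha=0.05
        rng = np.random.default_rng(12)
        n, reps = 300, 200
        rejections = 0
        t = rng.exponential(100, n)
        e = (rng.random(n) < 0.8).astype(int)
        for _ in range(reps):
            x = rng.standard_normal(n)
            if coxph_univariate(x, t, e).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_wald_option_close_to_score_at_moderate_effect(self):
        x, t, e = _cohort(seed=1, n=200, beta=0.3)
        score = coxph_univariate(x, t, e, test="score")
        wald = coxph_univariate(x, t, e, test="wald")
        assert wald.coef == score.coef
        assert wald.p_value == pytest.approx(score.p_value, abs=0.05)

    def test_degenerate_inputs_error(self):
        _, t, e = _cohort(seed=2, n=20)
        with pytest.raises(ValueError, match="zero-variance"):
            coxph_univariate(np.ones(20), t, e)
        with pytest.raises(ValueError, match="events"):
            coxph_univariate(np.arange(20.0), t, np.zeros(20, dtype=int))


class TestChi2Independence:
    def test_perfect_independence(self):
        chi2, p = chi2_independence([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_2x2_closed_form(self):
        # n (ad - bc)^2 / (r1 r2 c1 c2)
        a, b, c, d = 20, 10, 10, 20
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = chi2_independence([[a, b], [c, d]])
        assert chi2 == pytest.approx(expected, abs=1e-9)
        assert chi2 == pytest.approx(20 / 3, abs=1e-9)

    def test_2x3_uses_two_degrees_of_freedom(self):
        tab = [[10, 20, 30], [15, 10, 25]]
        chi2, p = chi2_independence(tab)
        assert p == pytest.approx(float(sps.chi2.sf(chi2, df=2)))

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi2_independence([[0, 0], [5, 5]])


class TestAssocStats:
    def test_pearson_identity(self):
        x = np.arange(10.0)
        r, _ = assoc_stats(x, x, kind="pearson")
        assert r == pytest.approx(1.0)

    def test_point_biserial_equals_pearson_on_01_coding(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        y = rng.binomial(1, 0.4, 50).astype(float)
        rpb, ppb = assoc_stats(x, y, kind="point_biserial")
        rp, pp = assoc_stats(x, y, kind="pearson")
        assert rpb == pytest.approx(rp, abs=1e-12)
        assert ppb == pytest.approx(pp, abs=1e-12)

    def test_welch_identical_samples_null(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        y = np.repeat([0.0, 1.0], 10)
        t, p = assoc_stats(x, y, kind="welch")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            assoc_stats(np.ones(5), np.arange(5.0), kind="pearson")


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_mann_whitney_midrank_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = 50
            scores = rng.standard_normal(n)
            scores[rng.random(n) < 0.3] = 0.0  # force ties
            labels = rng.binomial(1, 0.5, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            ranks = sps.rankdata(scores)
            n1 = labels.sum()
            u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
            assert roc_auc(scores, labels) == pytest.approx(
                u1 / (n1 * (n - n1)), abs=1e-12
            )

    def test_negation_symmetry(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(100)
        y = rng.binomial(1, 0.5, 100)
        assert roc_auc(-s, y) == pytest.approx(1 - roc_auc(s, y), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCompareSurvival:
    def test_curves_and_medians_per_group(self, clinical_10):
        t = clinical_10.data["time_days"].to_numpy()
        e = clinical_10.data["event"].to_numpy()
        labels = np.array([0] * 5 + [1] * 5)
        cmp = compare_survival(t, e, labels)
        assert set(cmp.group_sizes) == {0, 1}
        assert cmp.group_sizes[0] == 5
        for grid, surv in cmp.km_curves.values():
            assert surv[0] == 1.0
            assert np.all(np.diff(surv) <= 0)
        assert 0 <= cmp.p_value <= 1
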