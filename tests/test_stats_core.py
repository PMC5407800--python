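import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

from findcut.data_model import CutpointSet, encode_groups
from findcut.exceptions import (
    CohortValidationError,
    ConfigurationError,
    DegenerateDataError,
    FindcutError,
)
from findcut.stats_core import (
    chi2_test,
    classification_metrics,
    compute_auc,
    fit_cox,
    fit_logistic,
    km_estimate,
    logrank_test,
    lr_test,
)

from naive_reference import naive_auc, naive_cox_loglik, naive_logrank


def _assign(groups, k):
    """GroupAssignment with given ordinal groups via synthetic z."""
    groups = np.asarray(groups)
    cuts = CutpointSet(np.arange(1, k + 1) - 0.5)
    return encode_groups(groups.astype(float), cuts)


class TestFitCox:
    def test_symmetric_groups_give_zero_beta(self):
        # both groups carry the identical (time, event) multiset
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        fit = fit_cox(_assign([0, 0, 0, 1, 1, 1], 1), time, event)
        assert abs(fit.beta[0]) < 1e-6
        assert fit.loglik >= fit.loglik_null - 1e-9

    def test_matches_dense_grid_oracle(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 1, 1, 1])
        groups = np.array([1, 0, 1, 0, 1, 0])
        assign = _assign(groups, 1)
        fit = fit_cox(assign, time, event)
        X = assign.dummies
        grid = minimize_scalar(
            lambda b: -naive_cox_loglik(np.array([b]), X, time, event),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-8},
        )
        assert abs(fit.beta[0] - grid.x) < 1e-4
        np.testing.assert_allclose(fit.hr, np.exp(fit.beta))

    def test_monotone_likelihood_flagged_unconverged(self):
        # group 1 holds the earliest events: the partial likelihood is
        # monotone in beta and no finite maximizer exists
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        fit = fit_cox(_assign([1, 1, 0, 0], 1), time, event)
        assert not fit.converged

    def test_no_events_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_cox(_assign([0, 1], 1), np.array([1.0, 2.0]), np.array([0, 0]))

    def test_coding_invariance(self, survival_cohort):
        assign = encode_groups(survival_cohort.z, CutpointSet([20.0, 29.0]))
        a = fit_cox(assign, survival_cohort.time, survival_cohort.event, coding="cumulative")
        b = fit_cox(assign, survival_cohort.time, survival_cohort.event, coding="onehot")
        assert abs(a.loglik - b.loglik) < 1e-6
        assert abs(a.lrt().p - b.lrt().p) < 1e-8
        # cumulative betas are increments of the one-hot (vs reference) betas
        np.testing.assert_allclose(np.cumsum(a.beta), b.beta, atol=1e-5)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        res = logrank_test([0, 0, 0, 1, 1, 1], time, event)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_risk_table_recursion(self):
        # group A events at 1,2; group B events at 3,4
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        group = np.array([0, 0, 1, 1])
        res = logrank_test(group, time, event)
        assert res.statistic == pytest.approx(naive_logrank(group, time, event), abs=1e-10)
        assert res.df == 1

    def test_three_groups_df(self, survival_cohort):
        assign = encode_groups(survival_cohort.z, CutpointSet([20.0, 29.0]))
        res = logrank_test(assign.group, survival_cohort.time, survival_cohort.event)
        assert res.df == 2
        trend = logrank_test(
            assign.group, survival_cohort.time, survival_cohort.event, trend=True
        )
        assert trend.df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ConfigurationError):
            logrank_test([0, 0], np.array([1.0, 2.0]), np.array([1, 1]))


class TestFitLogistic:
    def test_saturated_closed_form(self):
        # group 0: 1/4 events, group 1: 3/4 events
        groups = np.array([0] * 4 + [1] * 4)
        y = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        fit = fit_logistic(_assign(groups, 1), y)
        assert fit.intercept == pytest.approx(np.log(1 / 3), abs=1e-6)
        assert fit.beta[0] == pytest.approx(2.1972246, abs=1e-5)
        assert fit.or_[0] == pytest.approx(9.0, rel=1e-4)
        np.testing.assert_allclose(fit.group_probs, [0.25, 0.75], atol=1e-8)

    def test_intercept_only_is_logit_of_mean(self):
        y = np.array([1, 1, 0, 0, 0])
        fit = fit_logistic(_assign([0] * 5, 0), y)
        assert fit.intercept == pytest.approx(np.log(0.4 / 0.6), abs=1e-6)
        assert fit.loglik == pytest.approx(fit.loglik_null, abs=1e-8)

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_logistic(_assign([0, 1], 1), np.array([0, 0]))

    def test_quasi_separation_flagged(self):
        groups = np.array([0] * 5 + [1] * 5)
        y = np.array([0, 1, 0, 1, 0] + [1] * 5)  # upper group all events
        fit = fit_logistic(_assign(groups, 1), y)
        assert not fit.converged

    def test_coding_invariance(self, binary_cohort):
        assign = encode_groups(binary_cohort.z, CutpointSet([20.0, 29.0]))
        a = fit_logistic(assign, binary_cohort.y, coding="cumulative")
        b = fit_logistic(assign, binary_cohort.y, coding="onehot")
        assert abs(a.loglik - b.loglik) < 1e-8
        np.testing.assert_allclose(a.group_probs, b.group_probs, atol=1e-8)


class TestLrTest:
    def test_equal_logliks(self):
        res = lr_test(-10.0, -10.0, df=1)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_saturated_example_closed_form(self):
        groups = np.array([0] * 4 + [1] * 4)
        y = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        fit = fit_logistic(_assign(groups, 1), y)
        ll_full = 2 * (xlogy(1, 0.25) + xlogy(3, 0.75))  # both groups, by symmetry
        ll_null = float(xlogy(4, 0.5) + xlogy(4, 0.5))
        res = fit.lrt()
        assert res.statistic == pytest.approx(2 * (ll_full - ll_null), abs=1e-6)

    def test_nesting_violation_raises(self):
        with pytest.raises(FindcutError):
            lr_test(-11.0, -10.0, df=1)


class TestAuc:
    @pytest.mark.parametrize(
        "score, y, expected",
        [
            ([1, 1, 1, 1], [0, 1, 0, 1], 0.5),  # constant scores: all ties
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ],
    )
    def test_known_values(self, score, y, expected):
        assert compute_auc(score, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 60))
            score = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert compute_auc(score, y) == pytest.approx(
                naive_auc(score, y), abs=1e-12
            )

    def test_single_class_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compute_auc([1.0, 2.0], [1, 1])


class TestKaplanMeier:
    def test_hand_example_with_censoring(self):
        curves = km_estimate([0, 0, 0], [1.0, 2.0, 3.0], [1, 0, 1])
        s = dict(zip(curves[0].times, curves[0].survival))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(1.0, 40).round(3)
        curves = km_estimate(np.zeros(40, int), t, np.ones(40, int))
        c = curves[0]
        for ti, si in zip(c.times, c.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-10)

    def test_empty_input_raises(self):
        with pytest.raises(DegenerateDataError):
            km_estimate([], [], [])


class TestChi2:
    def test_balanced_table_zero(self):
        res = chi2_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_direct_formula(self):
        res = chi2_test([[30, 10], [10, 30]])
        assert res.statistic == pytest.approx(20.0, abs=1e-10)
        assert res.df == 1

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateDataError):
            chi2_test([[0, 0], [10, 30]])


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        groups = np.array([0] * 5 + [1] * 5)
        y = np.array([0] * 5 + [1] * 5)
        fit = fit_logistic(_assign(groups, 1), y)
        # quasi-separated fit, but fitted group probabilities are 0/1
        m = classification_metrics(groups, y, fit)
        assert m["sensitivity"] == m["specificity"] == m["accuracy"] == 1.0
        assert m["sens_plus_spec"] == 2.0

    def test_derived_two_group_example(self):
        groups = np.array([0] * 5 + [1] * 5)
        y = np.array([1, 0, 0, 0, 0, 1, 1, 1, 1, 0])  # 1/5 and 4/5 events
        fit = fit_logistic(_assign(groups, 1), y)
        m = classification_metrics(groups, y, fit)
        assert m["sensitivity"] == pytest.approx(4 / 5)
        assert m["specificity"] == pytest.approx(4 / 5)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_chance_level_warns(self):
        groups = np.array([0, 0, 1, 1] * 5)
        y = np.array([0, 1, 0, 1] * 5)
        fit = fit_logistic(_assign(groups, 1), y)
        with pytest.warns(UserWarning):
            m = classification_metrics(groups, y, fit)
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["sens_plus_spec"] == pytest.approx(1.0)

    def test_top_group_rule(self, binary_cohort):
        assign = encode_groups(binary_cohort.z, CutpointSet([20.0, 29.0]))
        fit = fit_logistic(assign, binary_cohort.y)
        m = classification_metrics(assign.group, binary_cohort.y, fit, rule="top_group")
        assert 0 <= m["accuracy"] <= 1
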