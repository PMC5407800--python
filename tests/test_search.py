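import numpy as np
import pytest

from findcut.data_model import CutpointSet
from findcut.exceptions import ConfigurationError, NoFeasibleSplitError
from findcut.search import (
    CandidateGrid,
    candidate_cutpoints,
    chi2_baseline_search,
    search_cutpoints,
)

from conftest import make_cohort
from naive_reference import naive_search


class TestCandidateGrid:
    def test_min_group_frac_screens_edges(self):
        grid = candidate_cutpoints(np.arange(1.0, 11.0), min_group_frac=0.2)
        np.testing.assert_array_equal(grid.values, [3, 4, 5, 6, 7, 8, 9])

    def test_zero_frac_keeps_all_but_minimum(self):
        z = np.arange(1.0, 11.0)
        grid = candidate_cutpoints(z, min_group_frac=0.0)
        np.testing.assert_array_equal(grid.values, np.arange(2.0, 11.0))

    def test_constant_z_has_no_candidates(self):
        with pytest.raises(NoFeasibleSplitError):
            candidate_cutpoints(np.full(10, 3.0))

    def test_midpoint_grid(self):
        grid = candidate_cutpoints(np.array([1.0, 2.0, 4.0, 8.0]), min_group_frac=0.0,
                                   midpoints=True)
        np.testing.assert_allclose(grid.values, [1.5, 3.0, 6.0])


class TestSearchBasics:
    def test_forced_two_cut_outcome(self):
        # exactly 3 distinct values: the only feasible pair is the 2 boundaries
        z = np.repeat([1.0, 2.0, 3.0], 10)
        y = np.r_[np.ones(2), np.zeros(8), np.ones(5), np.zeros(5), np.ones(9), [0]].astype(int)
        cohort = make_cohort(z, y=y)
        res = search_cutpoints(cohort, 2, "logistic_lrt")
        assert res.best.cuts == (2.0, 3.0)
        assert res.surface["valid"].sum() == 1

    def test_incompatible_criterion_mode(self, binary_cohort, survival_cohort):
        with pytest.raises(ConfigurationError):
            search_cutpoints(binary_cohort, 1, "logrank")
        with pytest.raises(ConfigurationError):
            search_cutpoints(survival_cohort, 1, "max_auc")

    def test_no_feasible_split_raises(self):
        z = np.r_[np.full(19, 1.0), [2.0]]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        cohort = make_cohort(z, y=y)
        with pytest.raises(NoFeasibleSplitError):
            search_cutpoints(cohort, 1, "logistic_lrt")  # upper group has 1 subject

    def test_k2_tuple_count_is_binomial(self, binary_cohort):
        grid = candidate_cutpoints(binary_cohort.z, min_group_frac=0.1)
        res = search_cutpoints(binary_cohort, 2, "chi2", grid)
        m = len(grid)
        assert res.n_evaluated == m * (m - 1) // 2

    def test_deterministic_output(self, binary_cohort):
        a = search_cutpoints(binary_cohort, 2, "logistic_lrt")
        b = search_cutpoints(binary_cohort, 2, "logistic_lrt")
        assert a.best.cuts == b.best.cuts
        assert a.best_value == b.best_value


class TestMonotoneTransformEquivariance:
    @pytest.mark.parametrize("criterion", ["logrank", "cox_lrt"])
    def test_survival_criteria(self, survival_cohort, criterion):
        res = search_cutpoints(survival_cohort, 1, criterion)
        zt = np.log(survival_cohort.z)  # strictly increasing transform
        cohort_t = make_cohort(zt, time=survival_cohort.time, event=survival_cohort.event)
        res_t = search_cutpoints(cohort_t, 1, criterion)
        assert res_t.best.cuts[0] == pytest.approx(np.log(res.best.cuts[0]))
        assert res_t.best_value == pytest.approx(res.best_value, rel=1e-9)

    @pytest.mark.parametrize("criterion", ["logistic_lrt", "max_auc", "chi2"])
    def test_binary_criteria(self, binary_cohort, criterion):
        res = search_cutpoints(binary_cohort, 2, criterion)
        zt = np.sqrt(binary_cohort.z)
        cohort_t = make_cohort(zt, y=binary_cohort.y)
        res_t = search_cutpoints(cohort_t, 2, criterion)
        np.testing.assert_allclose(
            np.square(res_t.best.cuts), res.best.cuts, rtol=1e-12
        )
        assert res_t.best_value == pytest.approx(res.best_value, rel=1e-9)


class TestOracleEquivalence:
    """The vectorized scan must agree with the naive double-loop reference."""

    @pytest.mark.parametrize("criterion", ["logrank", "cox_lrt"])
    @pytest.mark.parametrize("k", [1, 2])
    def test_survival(self, survival_cohort, criterion, k):
        sub = survival_cohort.subset(survival_cohort.df.index[:120])
        grid = candidate_cutpoints(sub.z, min_group_frac=0.15)
        res = search_cutpoints(sub, k, criterion, grid)
        cuts, value = naive_search(
            sub.z, (sub.time, sub.event), k, criterion, grid.values,
            grid.min_group_size, grid.min_events_per_group,
        )
        assert res.best.cuts == tuple(cuts)
        assert res.best_value == pytest.approx(value, rel=1e-7)

    @pytest.mark.parametrize("criterion", ["logistic_lrt", "max_auc", "chi2"])
    @pytest.mark.parametrize("k", [1, 2])
    def test_binary(self, binary_cohort, criterion, k):
        sub = binary_cohort.subset(binary_cohort.df.index[:120])
        grid = candidate_cutpoints(sub.z, min_group_frac=0.15)
        res = search_cutpoints(sub, k, criterion, grid)
        cuts, value = naive_search(
            sub.z, sub.y, k, criterion, grid.values, grid.min_group_size
        )
        assert res.best.cuts == tuple(cuts)
        assert res.best_value == pytest.approx(value, rel=1e-7)


class TestChi2Baseline:
    def test_perfect_separation_statistic_is_n(self):
        # y perfectly separated by z at 0: a perfect balanced 2x2 gives X^2 = n
        z = np.r_[np.arange(-10.0, 0.0), np.arange(1.0, 11.0)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        cohort = make_cohort(z, y=y)
        res = chi2_baseline_search(cohort, 1)
        assert res.best.cuts == (1.0,)
        assert res.best_value == pytest.approx(20.0)

    def test_requires_binary_mode(self, survival_cohort):
        with pytest.raises(ConfigurationError):
            chi2_baseline_search(survival_cohort, 1)

    def test_null_statistic_small_and_matches_oracle(self, rng):
        z = rng.normal(size=120).round(1)
        y = rng.permutation(np.r_[np.zeros(60), np.ones(60)]).astype(int)
        cohort = make_cohort(z, y=y)
        grid = candidate_cutpoints(z, min_group_frac=0.15)
        res = chi2_baseline_search(cohort, 1, grid)
        cuts, value = naive_search(z, y, 1, "chi2", grid.values, grid.min_group_size)
        assert res.best.cuts == tuple(cuts)
        assert res.best_value == pytest.approx(value, abs=1e-10)
        assert res.best_value < 40.0  # far from the perfect-separation value n=120
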