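from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from oracles import (
    binomial_minlike_exact,
    fisher_minlike_exact,
    uniform_ellipse_major_fraction_mc,
)
from territoria.errors import DataError, UserError
from territoria.morphometry import nucleus_morphometry
from territoria.stats import (
    binomial_obs_vs_expected,
    coefficient_of_variation,
    expected_cell_class_probability,
    expected_major_fraction_ellipse,
    expected_major_fraction_mask,
    fisher_exact_2x2,
    holm_adjust,
    welch_t,
)
from territoria.synth import NucleusSpec, generate_nucleus


class TestEllipseNull:
    def test_circle_is_exactly_half(self):
        assert expected_major_fraction_ellipse(1.0, 1.0).p_major == 0.5
        assert expected_major_fraction_ellipse(7.3, 7.3).p_major == 0.5

    def test_strictly_increasing_in_axis_ratio(self):
        ratios = np.linspace(1.0, 3.0, 10)
        values = [expected_major_fraction_ellipse(r, 1.0).p_major for r in ratios]
        assert np.all(np.diff(values) > 0)

    def test_extreme_elongation_approaches_one(self):
        assert expected_major_fraction_ellipse(1e6, 1.0).p_major > 0.999

    def test_matches_monte_carlo_at_ratio_two(self):
        closed = expected_major_fraction_ellipse(2.0, 1.0).p_major
        mc = uniform_ellipse_major_fraction_mc(2.0, 1.0, 100_000, seed=0)
        assert closed == pytest.approx(mc, abs=3 * np.sqrt(0.25 / 100_000) + 1e-3)

    def test_mean_myoblast_axes_value(self):
        # frozen against a 10^6-point Monte-Carlo oracle (seed 0): 0.620
        assert expected_major_fraction_ellipse(12.8, 8.7).p_major == pytest.approx(
            0.620, abs=5e-4
        )

    def test_invalid_axes(self):
        with pytest.raises(UserError):
            expected_major_fraction_ellipse(1.0, 2.0)
        with pytest.raises(UserError):
            expected_major_fraction_ellipse(1.0, 0.0)


class TestMaskNull:
    def test_disc_mask_near_half(self):
        yy, xx = np.mgrid[0:120, 0:120]
        mask = (yy - 59.5) ** 2 + (xx - 59.5) ** 2 <= 40**2
        shape = nucleus_morphometry(mask, 0.13)
        null = expected_major_fraction_mask(mask, shape, n_mc=100_000, seed=1)
        assert abs(null.p_major - 0.5) <= 3 * null.se

    def test_two_to_one_ellipse_matches_closed_form(self):
        mask, _ = generate_nucleus(NucleusSpec(semi_major_px=50, semi_minor_px=25), (160, 160))
        shape = nucleus_morphometry(mask, 0.13)
        null = expected_major_fraction_mask(mask, shape, n_mc=100_000, seed=2)
        closed = expected_major_fraction_ellipse(2.0, 1.0).p_major
        assert abs(null.p_major - closed) <= 3 * null.se + 0.01

    def test_fixed_seed_is_deterministic(self):
        mask, _ = generate_nucleus(NucleusSpec(), (160, 160))
        shape = nucleus_morphometry(mask, 0.13)
        a = expected_major_fraction_mask(mask, shape, n_mc=1_000, seed=3)
        b = expected_major_fraction_mask(mask, shape, n_mc=1_000, seed=3)
        assert a.p_major == b.p_major

    def test_too_few_samples(self):
        mask, _ = generate_nucleus(NucleusSpec(), (160, 160))
        with pytest.raises(UserError):
            expected_major_fraction_mask(mask, nucleus_morphometry(mask, 0.13), n_mc=99)


class TestCellClassProbability:
    def test_normal_independent_halves(self):
        assert expected_cell_class_probability(0.5, "normal", 2) == 0.25
        assert expected_cell_class_probability(0.9, "normal", 2) == pytest.approx(0.01)

    def test_tumor_majority_of_four(self):
        # P(X >= 2), X ~ Bin(4, 0.5): 11 of the 16 equally likely outcomes
        assert expected_cell_class_probability(0.5, "tumor", 4) == pytest.approx(11 / 16)

    def test_scheme_n_mismatch(self):
        with pytest.raises(UserError):
            expected_cell_class_probability(0.5, "normal", 3)


class TestBinomialTest:
    def test_observed_equals_expected(self):
        assert binomial_obs_vs_expected(5, 10, 0.5).p_value == 1.0

    def test_all_successes(self):
        assert binomial_obs_vs_expected(10, 10, 0.5).p_value == pytest.approx(
            2 / 1024, abs=1e-15
        )

    @pytest.mark.parametrize("k,n,p0", [(0, 12, 0.25), (3, 17, 0.62), (9, 20, 0.5)])
    def test_matches_exact_enumeration(self, k, n, p0):
        expected = binomial_minlike_exact(k, n, Fraction(p0).limit_denominator(10**6))
        assert binomial_obs_vs_expected(k, n, p0).p_value == pytest.approx(
            expected, abs=1e-12
        )

    def test_cross_check_against_scipy(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 60))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            mine = binomial_obs_vs_expected(k, n, p0).p_value
            ref = sps.binomtest(k, n, p0).pvalue
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(UserError):
            binomial_obs_vs_expected(11, 10, 0.5)
        with pytest.raises(UserError):
            binomial_obs_vs_expected(5, 10, 1.0)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0

    def test_perfect_separation(self):
        from math import comb

        expected = 2 / comb(20, 10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]).p_value == pytest.approx(
            expected, abs=1e-15
        )

    def test_zero_row_is_uninformative(self):
        assert fisher_exact_2x2([[0, 0], [3, 7]]).p_value == 1.0

    @pytest.mark.parametrize("table", [[[3, 5], [8, 2]], [[1, 9], [4, 6]], [[7, 0], [2, 2]]])
    def test_matches_exact_enumeration(self, table):
        (a, b), (c, d) = table
        assert fisher_exact_2x2(table).p_value == pytest.approx(
            fisher_minlike_exact(a, b, c, d), abs=1e-12
        )

    def test_cross_check_against_scipy(self, rng):
        for _ in range(25):
            table = rng.integers(0, 15, size=(2, 2))
            if table.sum() == 0:
                continue
            mine = fisher_exact_2x2(table).p_value
            ref = sps.fisher_exact(table)[1]
            assert mine == pytest.approx(ref, abs=1e-7)

    def test_negative_counts_rejected(self):
        with pytest.raises(UserError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_equal_variance_case_reduces_to_pooled_t(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        welch = welch_t(a, b)
        pooled_t, pooled_p = sps.ttest_ind(a, b, equal_var=True)
        # equal n: Welch statistic coincides with the pooled statistic exactly
        assert welch.statistic == pytest.approx(float(pooled_t), abs=1e-12)

    def test_errors(self):
        with pytest.raises(UserError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(DataError):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_hand_computed_value(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_errors(self):
        with pytest.raises(DataError):
            coefficient_of_variation([-1.0, 1.0])


def test_holm_adjustment_monotone_and_bounded():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = holm_adjust(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.04)
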