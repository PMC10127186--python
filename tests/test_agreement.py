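"""Agreement kernel: ICC(C,1), Bland–Altman, OLS."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import footfall as ff
from footfall.agreement import icc_consistency, interpret_icc


def anova_icc_oracle(X):
    """Brute-force two-way ANOVA consistency ICC from first definitions.

    Sums of squares computed by explicit loops over cells; kept
    deliberately independent of the implementation under test.
    """
    n = len(X)
    k = len(X[0])
    grand = sum(sum(row) for row in X) / (n * k)
    row_means = [sum(row) / k for row in X]
    col_means = [sum(X[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = sum(k * (rm - grand) ** 2 for rm in row_means)
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


class TestIccConsistency:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(2, 9)
            k = rng.integers(2, 6)
            X = rng.normal(10, 3, size=(n, k))
            res = icc_consistency(X)
            assert res.icc == pytest.approx(anova_icc_oracle(X.tolist()), abs=1e-10)
            assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_icc3(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.normal(50, 12, size=(8, 3))
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": X.ravel(),
            })
            table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
            row = table.loc["ICC(C,1)" if "ICC(C,1)" in table.index else "ICC3"]
            ci = row["CI95" if "CI95" in row.index else "CI95%"]
            res = icc_consistency(X)
            assert res.icc == pytest.approx(row["ICC"], abs=1e-8)
            # pingouin rounds the CI bounds to 2 decimals
            assert res.ci_low == pytest.approx(ci[0], abs=6e-3)
            assert res.ci_high == pytest.approx(ci[1], abs=6e-3)

    def test_identical_raters(self):
        X = np.column_stack([[1, 4, 2, 9], [1, 4, 2, 9]])
        res = icc_consistency(X)
        assert res.icc == 1.0 and res.band == "excellent"

    def test_constant_rater_shift_is_perfect_consistency(self):
        col = np.array([3.0, 8.0, 1.0, 5.0, 7.0])
        res = icc_consistency(np.column_stack([col, col + 10.0]))
        assert res.icc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_zero_variance_flagged_degenerate(self):
        res = icc_consistency(np.full((4, 2), 7.0))
        assert res.degenerate and math.isnan(res.icc) and res.band is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_consistency(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_consistency(np.array([[1.0, np.nan], [2.0, 3.0]]))

    @given(st.floats(-50, 50))
    def test_invariant_to_shifting_one_rater(self, shift):
        X = np.array([[1.0, 2.0], [5.0, 4.5], [3.0, 3.5], [8.0, 9.0]])
        shifted = X.copy()
        shifted[:, 1] += shift
        assert icc_consistency(shifted).icc == pytest.approx(
            icc_consistency(X).icc, abs=1e-9)


@pytest.mark.parametrize("icc, band", [
    (0.49, "poor"), (-0.2, "poor"),
    (0.5, "moderate"), (0.75, "moderate"),
    (0.76, "good"), (0.80, "good"), (0.9, "good"),
    (0.95, "excellent"),
])
def test_interpret_icc_bands(icc, band):
    assert interpret_icc(icc) == band


class TestBlandAltman:
    def test_identical_methods(self):
        a = np.array([5.0, 9.0, 14.0])
        res = ff.bland_altman(a, a)
        assert res.mean_diff == 0 and (res.loa_low, res.loa_high) == (0, 0)
        assert res.mape == 0 and math.isnan(res.t_stat)

    def test_hand_computed_example(self):
        res = ff.bland_altman([9, 18, 27], [10, 20, 30])
        assert res.mean_diff == pytest.approx(-2.0)
        assert res.mape == pytest.approx(10.0)
        assert res.pct_diff == pytest.approx(-10.0)

    def test_reported_percentage_difference_identity(self):
        assert ff.percentage_difference(-4.65, 27.9) == pytest.approx(-16.667, abs=1e-2)

    def test_zero_reference_pairs_dropped_and_counted(self):
        res = ff.bland_altman([9, 18, 5], [10, 20, 0])
        assert res.n_zero_reference == 1
        assert res.mape == pytest.approx(10.0)

    def test_all_zero_reference_flagged(self):
        res = ff.bland_altman([1, 2, 3], [0, 0, 0])
        assert math.isnan(res.mape)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30),
           st.integers(0, 2 ** 31 - 1))
    def test_loa_definition(self, diffs, seed):
        b = np.random.default_rng(seed).uniform(1, 50, len(diffs))
        a = b + np.array(diffs)
        res = ff.bland_altman(a, b)
        assert res.loa_low == pytest.approx(res.mean_diff - 1.96 * res.sd_diff)
        assert res.loa_high == pytest.approx(res.mean_diff + 1.96 * res.sd_diff)

    def test_loa_cover_about_95_percent_of_normal_diffs(self):
        rng = np.random.default_rng(8)
        b = rng.uniform(20, 60, 20000)
        a = b + rng.normal(-3, 4, b.size)
        res = ff.bland_altman(a, b)
        inside = np.mean((a - b >= res.loa_low) & (a - b <= res.loa_high))
        assert 0.945 < inside < 0.955


def normal_equations_oracle(x, y):
    """Closed-form least squares via raw sums (independent of scipy)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestOls:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = ff.ols_fit(x, x)
        assert res.slope == pytest.approx(1.0) and res.intercept == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 5.2, 7.0, 9.0]  # y = 2x + 1 with one perturbed point
        res = ff.ols_fit(x, y)
        slope, intercept = normal_equations_oracle(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)

    def test_r_squared_is_squared_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(size=40)
        res = ff.ols_fit(x, y)
        assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        res = ff.ols_fit(x, y)
        assert res.slope_ci_low < 0 < res.slope_ci_high

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ff.ols_fit([1, 1, 1], [1, 2, 3])


class TestProportionalBias:
    def test_equal_methods_give_zero_slope(self):
        a = np.array([3.0, 9.0, 15.0, 30.0])
        res = ff.proportional_bias(a, a)
        assert res.slope == pytest.approx(0.0)

    def test_scaled_undercount_gives_negative_slope(self):
        b = np.array([10.0, 20.0, 40.0, 80.0])
        res = ff.proportional_bias(0.8 * b, b)
        assert res.slope < 0
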