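"""Agreement and reliability kernel.

First-principles implementations of the statistics shared by the
stability and validity analyses:

* ICC(C,1) — two-way mixed, single-measure, *consistency* intraclass
  correlation from the two-way ANOVA decomposition, with the F-based
  95% confidence interval (McGraw–Wong convention) and the usual
  interpretation bands (poor / moderate / good / excellent);
* Bland–Altman agreement: mean difference, sample-SD limits of
  agreement (1.96·SD literally), one-sample t-test for systematic bias,
  mean absolute percentage error and percentage difference;
* simple ordinary least squares with a t-based slope confidence
  interval, plus the proportional-bias regression of differences on
  pair means.

Differences are oriented ``a − b`` throughout; callers pass the sensor
as ``a`` and the reference (manual) method as ``b`` so an undercounting
sensor yields negative bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "IccResult",
    "BlandAltmanResult",
    "RegressionResult",
    "icc_consistency",
    "interpret_icc",
    "bland_altman",
    "percentage_difference",
    "ols_fit",
    "proportional_bias",
]

POOR, MODERATE, GOOD, EXCELLENT = "poor", "moderate", "good", "excellent"

# Relative tolerance below which residual variance is treated as exact
# agreement (guards float dust when one column is a constant shift of
# the other, where the consistency ICC is exactly 1 by definition).
_MS_ERROR_REL_TOL = 1e-12


def interpret_icc(icc: float) -> str:
    """Interpretation band: <0.5 poor, 0.5–0.75 moderate, (0.75, 0.9]
    good, >0.9 excellent.

    The half-open boundary at 0.75 follows the "good (ICC > 0.75)"
    convention, which resolves the gap the prose bands leave between
    0.75 and 0.76.
    """
    if not math.isfinite(icc):
        raise ValueError("ICC is not finite")
    if icc < 0.5:
        return POOR
    if icc <= 0.75:
        return MODERATE
    if icc <= 0.9:
        return GOOD
    return EXCELLENT


@lru_cache(maxsize=None)
def _f_critical(df1: int, df2: int, alpha: float) -> float:
    return float(stats.f.ppf(1.0 - alpha / 2.0, df1, df2))


@dataclass(frozen=True)
class IccResult:
    """Consistency ICC with its ANOVA mean squares and F-based CI."""

    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_error: float
    n_subjects: int
    n_raters: int
    band: str | None
    degenerate: bool = False


def icc_consistency(matrix, alpha: float = 0.05) -> IccResult:
    """ICC(C,1) of an ``n_subjects x n_raters`` measurement matrix.

    Two-way ANOVA decomposition with rater (column) effects removed:
    ``ICC = (MS_rows − MS_err) / (MS_rows + (k−1)·MS_err)``.  The CI
    comes from the F ratio ``MS_rows / MS_err`` with ``n−1`` and
    ``(n−1)(k−1)`` degrees of freedom.  A matrix with no variance at all
    has an undefined ICC and is returned flagged ``degenerate``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x raters)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")

    grand = X.mean()
    ss_rows = k * float(((X.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((X.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)

    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ms_rows <= 0.0 and ms_err <= 0.0:
        return IccResult(math.nan, math.nan, math.nan, ms_rows, ms_err,
                         n, k, band=None, degenerate=True)

    if ms_err <= _MS_ERROR_REL_TOL * ms_rows:
        # perfect consistency (e.g. one rater is a constant shift of another)
        return IccResult(1.0, 1.0, 1.0, ms_rows, ms_err, n, k,
                         band=interpret_icc(1.0))

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_rows / ms_err
    f_low = f_obs / _f_critical(df1, df2, alpha)
    f_high = f_obs * _f_critical(df2, df1, alpha)
    ci_low = (f_low - 1.0) / (f_low + k - 1.0)
    ci_high = (f_high - 1.0) / (f_high + k - 1.0)
    return IccResult(float(icc), float(ci_low), float(ci_high),
                     ms_rows, ms_err, n, k, band=interpret_icc(icc))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement summary for paired counts (a − b)."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    mape: float
    pct_diff: float
    n_zero_reference: int


def percentage_difference(mean_diff: float, reference_mean: float) -> float:
    """Mean difference as a percentage of the reference method's mean."""
    if reference_mean == 0:
        return math.nan
    return 100.0 * mean_diff / reference_mean


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman analysis of paired measurements ``a`` (test method)
    against ``b`` (reference method).

    Limits of agreement are mean ± 1.96 x sample SD of the differences.
    A one-sample t-test of the differences against zero quantifies
    systematic bias (undefined when the differences are constant).
    MAPE averages ``100·|a−b| / b`` over pairs with a nonzero reference;
    zero-reference pairs are dropped and counted in
    ``n_zero_reference`` (MAPE is NaN if none remain).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = a.size
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")

    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - loa_multiplier * sd_diff
    loa_high = mean_diff + loa_multiplier * sd_diff

    if sd_diff > 0:
        t_stat, p_value = stats.ttest_1samp(d, 0.0)
        t_stat, p_value = float(t_stat), float(p_value)
    else:
        t_stat, p_value = math.nan, math.nan

    nonzero = b != 0
    n_zero = int(np.count_nonzero(~nonzero))
    if nonzero.any():
        mape = float(np.mean(100.0 * np.abs(d[nonzero]) / b[nonzero]))
    else:
        mape = math.nan

    return BlandAltmanResult(
        n=n, mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=loa_low, loa_high=loa_high,
        t_stat=t_stat, p_value=p_value,
        mape=mape,
        pct_diff=percentage_difference(mean_diff, float(b.mean())),
        n_zero_reference=n_zero,
    )


@dataclass(frozen=True)
class RegressionResult:
    """Simple least-squares fit ``y = slope·x + intercept``."""

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def ols_fit(x, y, alpha: float = 0.05) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` with a t-based slope CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")

    res = stats.linregress(x, y)
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 2))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci_low=float(res.slope - t_crit * res.stderr),
        slope_ci_high=float(res.slope + t_crit * res.stderr),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=n,
    )


def proportional_bias(a, b, alpha: float = 0.05) -> RegressionResult:
    """Regress per-pair differences ``a − b`` on pair means ``(a+b)/2``.

    A nonzero slope signals proportional bias: the between-method
    difference grows (or shrinks) with the magnitude being measured.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return ols_fit((a + b) / 2.0, a - b, alpha=alpha)
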