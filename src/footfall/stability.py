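"""Behavioural stability of abbreviated monitoring schedules.

The core procedure: for each counter and meteorological season,
enumerate every possible combination of 1–4 complete monitored weeks,
summarise each combination as a weekday (Mon–Sun) median-count profile,
score it against the full season's weekday profile with the consistency
ICC, and aggregate the per-combination ICCs into a stability table
(mean ICC, 95% CI, number of combinations, interpretation band).

The ICC pairing treats the seven weekdays as subjects and the two
schedules (abbreviated subset vs entire season) as raters, i.e. each
combination is scored on a 7 x 2 matrix.  Because ICC(C,1) is a
consistency coefficient, an abbreviated schedule that reproduces the
season's day-of-week *shape* scores highly even if its level is offset.
Weeks containing missing or excluded days never enter a combination;
the season reference profile uses every retained day of the season,
including remainder days that belong to no week.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import IccResult, icc_consistency, interpret_icc
from .counts_io import (WEEKDAY_NAMES, CounterSeries, DailyCount, Season,
                        SeasonLayout, season_layouts)

__all__ = [
    "StabilityCell",
    "SeasonSummary",
    "enumerate_combinations",
    "day_of_week_profile",
    "week_profile_matrix",
    "score_combination",
    "season_stability",
    "stability_table",
]

DEFAULT_K_RANGE = (1, 2, 3, 4)


def enumerate_combinations(weeks: Sequence, k: int) -> list[tuple]:
    """All C(m, k) unordered subsets of the complete weeks, in
    deterministic lexicographic order.  ``k`` larger than the number of
    available weeks yields an empty list with a warning."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(weeks):
        warnings.warn(f"k={k} exceeds the {len(weeks)} complete weeks available;"
                      " no combinations", stacklevel=2)
        return []
    return list(itertools.combinations(weeks, k))


def day_of_week_profile(records: Iterable[DailyCount]) -> np.ndarray:
    """7-vector of median daily totals by weekday (Monday..Sunday)."""
    buckets: list[list[float]] = [[] for _ in range(7)]
    for r in records:
        if r.total is None:
            continue
        buckets[r.date.weekday()].append(float(r.total))
    empty = [WEEKDAY_NAMES[i] for i, b in enumerate(buckets) if not b]
    if empty:
        raise ValueError(f"no retained days on: {', '.join(empty)}")
    return np.array([np.median(b) for b in buckets])


def week_profile_matrix(layout: SeasonLayout) -> np.ndarray:
    """``m_complete x 7`` matrix: row w, column d is the total recorded
    on weekday d during the w-th complete week."""
    m = len(layout.complete_weeks)
    W = np.empty((m, 7))
    for row, wi in enumerate(layout.complete_weeks):
        for r in layout.weeks[wi]:
            W[row, r.date.weekday()] = float(r.total)
    return W


def score_combination(subset_profile, season_profile) -> IccResult:
    """Consistency ICC of an abbreviated-schedule weekday profile against
    the full-season weekday profile (7 subjects x 2 raters)."""
    subset_profile = np.asarray(subset_profile, dtype=float)
    season_profile = np.asarray(season_profile, dtype=float)
    if subset_profile.shape != (7,) or season_profile.shape != (7,):
        raise ValueError("profiles must be length-7 vectors")
    return icc_consistency(np.column_stack([subset_profile, season_profile]))


@dataclass(frozen=True)
class StabilityCell:
    """One counter x season x k entry of the stability table."""

    counter_id: str
    season: Season
    k_weeks: int
    mean_icc: float
    ci_low: float
    ci_high: float
    n_combinations: int
    band: str | None

    @property
    def available(self) -> bool:
        return self.n_combinations > 0


@dataclass(frozen=True)
class SeasonSummary:
    """Season-level descriptives over retained days only."""

    counter_id: str
    season: Season
    retained_days: int
    median_daily_count: float
    iqr_daily_count: float


def _season_summary(series: CounterSeries, layout: SeasonLayout) -> SeasonSummary:
    totals = np.array([r.total for r in layout.season_records()
                       if series.is_retained(r)], dtype=float)
    q1, q3 = np.quantile(totals, [0.25, 0.75]) if totals.size else (np.nan, np.nan)
    return SeasonSummary(
        counter_id=series.counter_id,
        season=layout.season,
        retained_days=int(totals.size),
        median_daily_count=float(np.median(totals)) if totals.size else np.nan,
        iqr_daily_count=float(q3 - q1),
    )


def season_stability(series: CounterSeries, layout: SeasonLayout,
                     k_range: Sequence[int] = DEFAULT_K_RANGE,
                     ci_method: str = "mean_f",
                     ) -> tuple[list[StabilityCell], SeasonSummary]:
    """Stability cells for one counter-season.

    ``ci_method`` selects how per-combination uncertainty is aggregated:
    ``"mean_f"`` (default) averages the per-combination F-based CI
    bounds; ``"percentile"`` takes the empirical 2.5th/97.5th
    percentiles of the combination ICCs.
    """
    if ci_method not in ("mean_f", "percentile"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    retained = [r for r in layout.season_records() if series.is_retained(r)]
    season_profile = day_of_week_profile(retained)
    W = week_profile_matrix(layout)
    m = W.shape[0]

    cells = []
    for k in k_range:
        if k > m:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                enumerate_combinations(range(m), k)
            cells.append(StabilityCell(series.counter_id, layout.season, k,
                                       np.nan, np.nan, np.nan, 0, None))
            continue
        combos = enumerate_combinations(range(m), k)
        iccs = np.empty(len(combos))
        lows = np.empty(len(combos))
        highs = np.empty(len(combos))
        for i, combo in enumerate(combos):
            subset_profile = np.median(W[list(combo)], axis=0)
            res = score_combination(subset_profile, season_profile)
            iccs[i], lows[i], highs[i] = res.icc, res.ci_low, res.ci_high
        # combinations with no variance at all (constant counts) have an
        # undefined ICC and drop out of the aggregate
        defined = np.isfinite(iccs)
        if defined.any():
            mean_icc = float(np.mean(iccs[defined]))
            if ci_method == "mean_f":
                ci_low = float(np.mean(lows[defined]))
                ci_high = float(np.mean(highs[defined]))
            else:
                ci_low, ci_high = (float(v) for v in
                                   np.percentile(iccs[defined], [2.5, 97.5]))
            band = interpret_icc(mean_icc)
        else:
            mean_icc = ci_low = ci_high = float("nan")
            band = None
        cells.append(StabilityCell(series.counter_id, layout.season, k,
                                   mean_icc, ci_low, ci_high, len(combos),
                                   band))
    return cells, _season_summary(series, layout)


def stability_table(series_list: list[CounterSeries],
                    k_range: Sequence[int] = DEFAULT_K_RANGE,
                    ci_method: str = "mean_f") -> pd.DataFrame:
    """Stability table across counters and seasons.

    One row per counter x season x k with the season descriptives
    repeated, mirroring the layout used to report abbreviated-schedule
    stability (median/IQR of retained daily counts, mean ICC with 95%
    CI, number of combinations, band).  Screening should already have
    been applied to the series.
    """
    rows = []
    for series in series_list:
        for season, layout in season_layouts(series).items():
            cells, summary = season_stability(series, layout, k_range, ci_method)
            for cell in cells:
                rows.append({
                    "counter_id": series.counter_id,
                    "season": season.value,
                    "retained_days": summary.retained_days,
                    "median_daily_count": summary.median_daily_count,
                    "iqr_daily_count": summary.iqr_daily_count,
                    "k_weeks": cell.k_weeks,
                    "mean_icc": cell.mean_icc,
                    "ci_low": cell.ci_low,
                    "ci_high": cell.ci_high,
                    "n_combinations": cell.n_combinations,
                    "band": cell.band,
                })
    return pd.DataFrame(rows)
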