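"""Exclusion screening for daily footfall series.

Applies the protocol used before the stability analysis: 3 x IQR
extreme-outlier detection on each counter's full monitored series,
cross-referencing against public-holiday and site-event calendars, and
the asymmetric removal rules (holidays excluded everywhere; event days
excluded only where they produced an extreme outlier; remaining
outliers excluded as unexplained).

Quartiles are computed once on the full pre-exclusion, non-missing
series with the linear-interpolation quantile definition, so screening
is single-pass and idempotent.  Values exactly on a fence are kept
("more than" three IQRs is a strict inequality); both fences are
checked.  Missing days never enter the quartile computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import CounterSeries, EventCalendar

__all__ = [
    "ExclusionReport",
    "compute_quartiles",
    "detect_extreme_outliers",
    "classify_and_exclude",
    "screen_counters",
]

DEFAULT_MULTIPLIER = 3.0

KEPT = "kept"
HOLIDAY = "holiday"
EVENT = "event"
UNEXPLAINED = "unexplained_outlier"


def compute_quartiles(values) -> tuple[float, float, float]:
    """(Q1, Q3, IQR) with linear-interpolation quantiles."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q1), float(q3), float(q3 - q1)


def detect_extreme_outliers(values, multiplier: float = DEFAULT_MULTIPLIER) -> set[int]:
    """Indices of values strictly outside quartile +/- multiplier x IQR.

    Requires at least 4 values so the quartiles are meaningful.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError(f"need >= 4 values to screen, got {values.size}")
    q1, q3, iqr = compute_quartiles(values)
    mask = (values > q3 + multiplier * iqr) | (values < q1 - multiplier * iqr)
    return set(np.nonzero(mask)[0].tolist())


@dataclass
class ExclusionReport:
    """Per-date screening decisions for one counter.

    ``decisions`` covers every non-missing monitored date; the retained
    count plus the excluded count equals the number of monitored
    non-missing days.
    """

    counter_id: str
    decisions: dict  # date -> KEPT | HOLIDAY | EVENT | UNEXPLAINED
    q1: float
    q3: float
    iqr: float
    multiplier: float

    @property
    def retained_days(self) -> int:
        return sum(1 for d in self.decisions.values() if d == KEPT)

    @property
    def excluded_days(self) -> int:
        return len(self.decisions) - self.retained_days

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "counter_id": self.counter_id,
            "date": [d.isoformat() for d in sorted(self.decisions)],
            "decision": [self.decisions[d] for d in sorted(self.decisions)],
        })


def classify_and_exclude(series: CounterSeries, calendar: EventCalendar,
                         multiplier: float = DEFAULT_MULTIPLIER) -> ExclusionReport:
    """Screen one counter and record its exclusions in place.

    Rules, in precedence order per date:

    1. public holidays are excluded regardless of outlier status (a date
       that is both holiday and event counts as holiday);
    2. event days are excluded only when the counter's total that day is
       an extreme outlier;
    3. any remaining extreme outlier is excluded as unexplained.
    """
    observed = [r for r in series.records if not r.missing]
    totals = [r.total for r in observed]
    outlier_idx = detect_extreme_outliers(totals, multiplier)
    q1, q3, iqr = compute_quartiles(totals)

    decisions = {}
    exclusions = {}
    for i, rec in enumerate(observed):
        if rec.date in calendar.holidays:
            decision = HOLIDAY
        elif rec.date in calendar.events and i in outlier_idx:
            decision = EVENT
        elif i in outlier_idx:
            decision = UNEXPLAINED
        else:
            decision = KEPT
        decisions[rec.date] = decision
        if decision != KEPT:
            exclusions[rec.date] = decision
    series.exclusions = exclusions
    return ExclusionReport(series.counter_id, decisions, q1, q3, iqr, multiplier)


def screen_counters(series_list: list[CounterSeries], calendar: EventCalendar,
                    multiplier: float = DEFAULT_MULTIPLIER) -> list[ExclusionReport]:
    """Screen every counter against the shared calendar."""
    return [classify_and_exclude(s, calendar, multiplier) for s in series_list]
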