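"""Tabular I/O and calendar layout for daily footfall counter exports.

Reads and writes the four CSV inputs of the analysis pipeline (daily
directional counts, paired manual/sensor observation sessions, a
holiday/event calendar, and daily weather), sums directional counts to
daily footfall, assigns meteorological seasons, and lays each monitored
season out as up to 13 candidate 7-day weeks for the stability analysis.

CSV dialects (UTF-8, header row, ISO-8601 dates):

* daily counts:   ``counter_id,date,count_a,count_b`` (blank counts = missing day)
* weather:        ``date,temp_c,rain_in,wind_mph``
* calendar:       ``date,kind,label`` with ``kind`` in ``{holiday, event}``
* sessions:       see :mod:`footfall.validity`
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Season",
    "DailyCount",
    "CounterSeries",
    "SeasonLayout",
    "WeatherDay",
    "EventCalendar",
    "MAX_WEEKS_PER_SEASON",
    "assign_season",
    "layout_season",
    "season_layouts",
    "weather_summary",
    "format_weather_summary",
    "read_daily_counts",
    "write_daily_counts",
    "read_weather",
    "write_weather",
    "read_calendar",
    "write_calendar",
    "read_sessions",
    "write_sessions",
]

MAX_WEEKS_PER_SEASON = 13

WEEKDAY_NAMES = ("Monday", "Tuesday", "Wednesday", "Thursday",
                 "Friday", "Saturday", "Sunday")


class Season(str, Enum):
    """Meteorological season (whole three-month blocks)."""

    SPRING = "Spring"
    SUMMER = "Summer"
    AUTUMN = "Autumn"
    WINTER = "Winter"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SEASON_ORDER = (Season.SPRING, Season.SUMMER, Season.AUTUMN, Season.WINTER)

_SEASON_BY_MONTH = {
    3: Season.SPRING, 4: Season.SPRING, 5: Season.SPRING,
    6: Season.SUMMER, 7: Season.SUMMER, 8: Season.SUMMER,
    9: Season.AUTUMN, 10: Season.AUTUMN, 11: Season.AUTUMN,
    12: Season.WINTER, 1: Season.WINTER, 2: Season.WINTER,
}


def assign_season(date: dt.date) -> tuple[Season, str]:
    """Map a calendar date to its meteorological season and year label.

    Spring = Mar 1 – May 31, Summer = Jun 1 – Aug 31, Autumn = Sep 1 –
    Nov 30, Winter = Dec 1 – Feb 28/29.  Winter is labelled with the year
    of its December, so 2022-01-10 belongs to Winter "2021".
    """
    season = _SEASON_BY_MONTH[date.month]
    year = date.year
    if season is Season.WINTER and date.month <= 2:
        year -= 1
    return season, str(year)


@dataclass(frozen=True)
class DailyCount:
    """One counter-day: directional beam-break counts or a missing day."""

    counter_id: str
    date: dt.date
    count_a: int | None
    count_b: int | None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            if self.count_a is not None or self.count_b is not None:
                raise ValueError(f"{self.counter_id} {self.date}: missing day carries counts")
        else:
            if self.count_a is None or self.count_b is None:
                raise ValueError(f"{self.counter_id} {self.date}: non-missing day lacks counts")
            if self.count_a < 0 or self.count_b < 0:
                raise ValueError(f"{self.counter_id} {self.date}: negative count")

    @property
    def total(self) -> int | None:
        """Total daily footfall: the two directional counts summed."""
        if self.missing:
            return None
        return self.count_a + self.count_b


@dataclass
class CounterSeries:
    """Date-ordered daily counts for one counter, with exclusion labels.

    ``exclusions`` maps a date to one of ``holiday``, ``event`` or
    ``unexplained_outlier`` once screening has run; dates absent from the
    map are retained (missing days are tracked on the records themselves).
    """

    counter_id: str
    records: list[DailyCount]
    exclusions: dict[dt.date, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dates = [r.date for r in self.records]
        for prev, nxt in zip(dates, dates[1:]):
            if nxt <= prev:
                raise ValueError(
                    f"{self.counter_id}: dates not strictly increasing at {nxt}")

    def __len__(self) -> int:
        return len(self.records)

    def is_retained(self, record: DailyCount) -> bool:
        return not record.missing and record.date not in self.exclusions

    def retained(self) -> list[DailyCount]:
        """Records that are neither missing nor excluded."""
        return [r for r in self.records if self.is_retained(r)]

    def observed_totals(self) -> np.ndarray:
        """Totals of all non-missing days (pre-exclusion), in date order."""
        return np.array([r.total for r in self.records if not r.missing], dtype=float)

    def retained_totals(self) -> np.ndarray:
        return np.array([r.total for r in self.retained()], dtype=float)


@dataclass(frozen=True)
class WeatherDay:
    """Daily weather record: mean temperature (C), total rainfall (inches),
    mean wind speed (mph)."""

    date: dt.date
    temp_c: float
    rain_in: float
    wind_mph: float

    def __post_init__(self) -> None:
        if self.rain_in < 0:
            raise ValueError(f"{self.date}: negative rainfall")
        if self.wind_mph < 0:
            raise ValueError(f"{self.date}: negative wind speed")


@dataclass(frozen=True)
class EventCalendar:
    """Public-holiday and site-event dates used by the screening rules."""

    holidays: frozenset[dt.date]
    events: frozenset[dt.date]
    labels: dict[tuple[dt.date, str], str] = field(default_factory=dict)


@dataclass
class SeasonLayout:
    """One monitored meteorological season partitioned into 7-day weeks.

    Weeks anchor at the first monitored day of the season (not ISO weeks)
    and are consecutive 7-day blocks of the season's monitored days, at
    most 13 per season; days beyond 13 x 7 stay in ``remainder`` and
    contribute to season-level statistics but to no week.
    ``complete_weeks`` indexes the blocks whose 7 days are all retained
    (non-missing, non-excluded) and cover all seven weekdays.
    """

    season: Season
    year_label: str
    day_range: tuple[dt.date, dt.date]
    weeks: list[list[DailyCount]]
    remainder: list[DailyCount]
    complete_weeks: list[int]

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    @property
    def n_complete(self) -> int:
        return len(self.complete_weeks)

    def season_records(self) -> list[DailyCount]:
        out: list[DailyCount] = []
        for week in self.weeks:
            out.extend(week)
        out.extend(self.remainder)
        return out


def layout_season(series: CounterSeries, season: Season,
                  year_label: str | None = None) -> SeasonLayout:
    """Partition a series' monitored days in one season into 7-day weeks.

    With ``year_label=None`` all of the series' days in that season are
    pooled chronologically (a monitoring year that starts mid-season
    contributes two segments of the same season).  Completeness of a week
    requires every one of its 7 days to be retained under the series'
    current exclusions, so screening should normally run first.
    """
    season = Season(season)
    recs = []
    labels = set()
    for r in series.records:
        s, y = assign_season(r.date)
        if s is season and (year_label is None or y == year_label):
            recs.append(r)
            labels.add(y)
    if not recs:
        raise ValueError(f"{series.counter_id}: no monitored days in {season.value}"
                         + (f" {year_label}" if year_label else ""))

    n_weeks = min(len(recs) // 7, MAX_WEEKS_PER_SEASON)
    weeks = [recs[i * 7:(i + 1) * 7] for i in range(n_weeks)]
    remainder = recs[n_weeks * 7:]
    complete = []
    for i, week in enumerate(weeks):
        weekdays = {r.date.weekday() for r in week}
        if len(weekdays) == 7 and all(series.is_retained(r) for r in week):
            complete.append(i)
    return SeasonLayout(
        season=season,
        year_label="/".join(sorted(labels)),
        day_range=(recs[0].date, recs[-1].date),
        weeks=weeks,
        remainder=remainder,
        complete_weeks=complete,
    )


def season_layouts(series: CounterSeries) -> dict[Season, SeasonLayout]:
    """Lay out every season present in the series, pooled across years."""
    present = {assign_season(r.date)[0] for r in series.records}
    return {s: layout_season(series, s) for s in SEASON_ORDER if s in present}


# ---------------------------------------------------------------------------
# Weather descriptives


def weather_summary(days: list[WeatherDay]) -> pd.DataFrame:
    """Per-season mean, sample sd, min and max of each weather variable.

    Returns a DataFrame indexed by season with a (variable, statistic)
    column MultiIndex; seasons appear in meteorological order.
    """
    if not days:
        raise ValueError("no weather days supplied")
    df = pd.DataFrame({
        "season": [assign_season(d.date)[0].value for d in days],
        "temp_c": [d.temp_c for d in days],
        "rain_in": [d.rain_in for d in days],
        "wind_mph": [d.wind_mph for d in days],
    })
    out = df.groupby("season")[["temp_c", "rain_in", "wind_mph"]].agg(
        ["mean", "std", "min", "max"])
    order = [s.value for s in SEASON_ORDER if s.value in out.index]
    return out.loc[order]


def format_weather_summary(summary: pd.DataFrame, digits: int = 3) -> pd.DataFrame:
    """Render a :func:`weather_summary` frame as ``mean +/- sd (min - max)``."""
    def fmt(x: float) -> str:
        return f"{x:.{digits}g}"

    cells = {}
    for var in ("temp_c", "rain_in", "wind_mph"):
        col = []
        for season in summary.index:
            m, s, lo, hi = (summary.loc[season, (var, stat)]
                            for stat in ("mean", "std", "min", "max"))
            sd = "nan" if pd.isna(s) else fmt(s)
            col.append(f"{fmt(m)} ± {sd} ({fmt(lo)} – {fmt(hi)})")
        cells[var] = col
    return pd.DataFrame(cells, index=summary.index)


# ---------------------------------------------------------------------------
# CSV readers / writers


def _parse_date(value, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except (TypeError, ValueError) as exc:
        raise ValueError(f"line {line}: unparseable date {value!r}") from exc


def _parse_count(value, line: int) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        count = int(text)
    except ValueError as exc:
        raise ValueError(f"line {line}: non-integer count {value!r}") from exc
    if count < 0:
        raise ValueError(f"line {line}: negative count {count}")
    return count


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def read_daily_counts(path) -> list[CounterSeries]:
    """Read a daily-counts CSV into one :class:`CounterSeries` per counter.

    Dates absent inside a counter's monitored range are materialised as
    ``missing=True`` records; rows with blank counts are missing days.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, {"counter_id", "date", "count_a", "count_b"}, path)
    per_counter: dict[str, dict[dt.date, tuple[int | None, int | None]]] = {}
    for line, row in enumerate(df.itertuples(index=False), start=2):
        cid = str(row.counter_id).strip()
        date = _parse_date(row.date, line)
        a = _parse_count(row.count_a, line)
        b = _parse_count(row.count_b, line)
        if (a is None) != (b is None):
            raise ValueError(f"line {line}: one directional count blank, the other not")
        days = per_counter.setdefault(cid, {})
        if date in days:
            raise ValueError(f"line {line}: duplicate date {date} for counter {cid}")
        days[date] = (a, b)

    out = []
    for cid in sorted(per_counter):
        days = per_counter[cid]
        first, last = min(days), max(days)
        records = []
        date = first
        while date <= last:
            a, b = days.get(date, (None, None))
            missing = a is None
            records.append(DailyCount(cid, date, a, b, missing=missing))
            date += dt.timedelta(days=1)
        out.append(CounterSeries(cid, records))
    return out


def write_daily_counts(series_list: list[CounterSeries], path) -> None:
    rows = []
    for series in series_list:
        for r in series.records:
            rows.append({
                "counter_id": r.counter_id,
                "date": r.date.isoformat(),
                "count_a": "" if r.missing else r.count_a,
                "count_b": "" if r.missing else r.count_b,
            })
    pd.DataFrame(rows, columns=["counter_id", "date", "count_a", "count_b"]).to_csv(
        path, index=False)


def read_weather(path) -> list[WeatherDay]:
    df = pd.read_csv(path)
    _require_columns(df, {"date", "temp_c", "rain_in", "wind_mph"}, path)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        out.append(WeatherDay(
            date=_parse_date(row.date, line),
            temp_c=float(row.temp_c),
            rain_in=float(row.rain_in),
            wind_mph=float(row.wind_mph),
        ))
    return out


def write_weather(days: list[WeatherDay], path) -> None:
    pd.DataFrame({
        "date": [d.date.isoformat() for d in days],
        "temp_c": [d.temp_c for d in days],
        "rain_in": [d.rain_in for d in days],
        "wind_mph": [d.wind_mph for d in days],
    }).to_csv(path, index=False)


def read_calendar(path) -> EventCalendar:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, {"date", "kind", "label"}, path)
    holidays, events, labels = set(), set(), {}
    for line, row in enumerate(df.itertuples(index=False), start=2):
        date = _parse_date(row.date, line)
        kind = str(row.kind).strip()
        if kind == "holiday":
            holidays.add(date)
        elif kind == "event":
            events.add(date)
        else:
            raise ValueError(f"line {line}: unknown calendar kind {kind!r}")
        labels[(date, kind)] = "" if pd.isna(row.label) else str(row.label)
    return EventCalendar(frozenset(holidays), frozenset(events), labels)


def write_calendar(calendar: EventCalendar, path) -> None:
    rows = []
    for date in sorted(calendar.holidays):
        rows.append({"date": date.isoformat(), "kind": "holiday",
                     "label": calendar.labels.get((date, "holiday"), "")})
    for date in sorted(calendar.events):
        rows.append({"date": date.isoformat(), "kind": "event",
                     "label": calendar.labels.get((date, "event"), "")})
    pd.DataFrame(rows, columns=["date", "kind", "label"]).to_csv(path, index=False)


def read_sessions(path):
    """Read paired manual/sensor observation sessions.

    Columns: ``session_id,date,start_hour,direction,manual_count,
    sensor_count,n_groups,n_below_height``; one row per session x direction.
    """
    from .validity import ObservationSession

    df = pd.read_csv(path, dtype=str)
    _require_columns(df, {"session_id", "date", "start_hour", "direction",
                          "manual_count", "sensor_count", "n_groups",
                          "n_below_height"}, path)
    out = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        out.append(ObservationSession(
            session_id=str(row.session_id),
            date=_parse_date(row.date, line),
            start_hour=int(row.start_hour),
            direction=str(row.direction).strip(),
            manual_count=int(row.manual_count),
            sensor_count=int(row.sensor_count),
            n_groups=int(row.n_groups),
            n_below_height=int(row.n_below_height),
        ))
    return out


def write_sessions(sessions, path) -> None:
    pd.DataFrame([{
        "session_id": s.session_id,
        "date": s.date.isoformat(),
        "start_hour": s.start_hour,
        "direction": s.direction,
        "manual_count": s.manual_count,
        "sensor_count": s.sensor_count,
        "n_groups": s.n_groups,
        "n_below_height": s.n_below_height,
    } for s in sessions]).to_csv(path, index=False)
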