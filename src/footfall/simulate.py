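"""Synthetic-data generator for counter, weather, calendar and session inputs.

Emulates a year of automated active infrared counter monitoring on park
footpaths, together with the paired one-hour manual-observation battery
used for validity testing, and records full ground truth so recovery
tests can check what the pipeline estimates against what was injected.

Daily counts follow a log-linear rate model: a per-counter base rate is
modulated by multiplicative weekday and season effects and by weather
covariates (temperature, rainfall, wind) acting on the log rate; totals
are drawn negative-binomially (overdispersed counts are typical of
footfall) and split 50/50 binomially between the two directions.
Public holidays and site events multiply the rate, tamper spikes
replace a day's count with a value far above the outlier fence, and
missing days are blanked at random.

Observation sessions use a pure occlusion model: group-units arrive as
a Poisson process; each unit has a truncated-geometric size; members
below the beam height are tallied but never sensed; the first
above-height member of a unit always breaks the beam and each further
member registers separately with probability ``p_separate``.  The
sensor can therefore only undercount — never overcount — which matches
a beam counter's binary count/no-count behaviour.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .counts_io import (CounterSeries, DailyCount, EventCalendar, Season,
                        WeatherDay, assign_season)
from .validity import ObservationSession

__all__ = [
    "SimConfig",
    "SimTruth",
    "SessionTruth",
    "SimulatedYear",
    "simulate_daily_counts",
    "simulate_sessions",
    "group_size_pmf",
    "expected_group_undercount",
    "expected_manual_rate",
    "write_simulation",
]

# Seasonal weather climatology: mean and sd of daily mean temperature (C),
# mean daily rainfall (in), mean and sd of daily mean wind speed (mph).
WEATHER_CLIMATE = {
    Season.SPRING: {"temp": (9.74, 2.88), "rain": 0.04, "wind": (2.56, 1.35)},
    Season.SUMMER: {"temp": (17.5, 2.39), "rain": 0.07, "wind": (2.01, 1.11)},
    Season.AUTUMN: {"temp": (13.1, 4.88), "rain": 0.05, "wind": (2.15, 1.28)},
    Season.WINTER: {"temp": (6.64, 2.97), "rain": 0.08, "wind": (3.32, 1.96)},
}

_RAIN_WET_PROB = 0.4  # rainfall is zero-inflated: dry days are common

# England bank holidays falling inside a May 2021 - May 2022 monitoring year.
DEFAULT_HOLIDAYS = (
    dt.date(2021, 5, 31), dt.date(2021, 8, 30),
    dt.date(2021, 12, 27), dt.date(2021, 12, 28),
    dt.date(2022, 1, 3), dt.date(2022, 4, 15), dt.date(2022, 4, 18),
    dt.date(2022, 5, 2),
)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults emulate the study conditions.

    Daily-count model
    -----------------
    base_rates : counts/day per counter at reference weather on a
        reference weekday; the three defaults span busy paved path to
        quiet woodland path.
    weekday_effects : Mon..Sun multipliers (weekends busier).
    season_effects : Spring/Summer/Autumn/Winter multipliers.
    weather_betas : (temp, rain, wind) effects on the log rate, per
        degree C (centred at 12), per inch, per mph (centred at 2.5).
    dispersion : negative-binomial overdispersion (variance =
        mu + dispersion * mu^2); 0 gives Poisson counts and
        ``deterministic_counts`` removes count noise entirely.
    tamper_magnitude : injected tamper values sit this many IQRs above
        the counter's Q3 (well outside the 3 x IQR screening fence).

    Session model
    -------------
    arrival_rate : group-units per hour per direction.
    arrival_cv : coefficient of variation of a gamma busy-ness
        multiplier drawn once per session and shared by both
        directions; park footfall varies strongly over the day, so
        hourly manual counts span a wide range.  0 disables it.
    group_p / group_max : truncated-geometric group-size law on
        {1..group_max}; p=0.7 gives mean size ~1.43.
    p_separate : probability a non-lead above-height member breaks the
        beam separately instead of being occluded.
    p_below_height : probability a member is below beam height.
    """

    seed: int = 0
    start_date: dt.date = dt.date(2021, 5, 4)
    n_days: int = 365
    n_counters: int = 3
    base_rates: tuple[float, ...] = (225.0, 115.0, 85.0)
    weekday_effects: tuple[float, ...] = (0.92, 0.90, 0.95, 0.97, 1.05, 1.30, 1.20)
    season_effects: tuple[float, float, float, float] = (1.05, 1.30, 1.00, 0.85)
    weather_betas: tuple[float, float, float] = (0.012, -0.8, -0.02)
    dispersion: float = 0.06
    deterministic_counts: bool = False
    holidays: tuple[dt.date, ...] = DEFAULT_HOLIDAYS
    holiday_multiplier: float = 2.2
    n_events: int = 4
    event_multiplier: float = 3.0
    event_counters: tuple[int, ...] = (0,)
    p_missing_day: float = 0.01
    n_tamper_spikes: int = 3
    tamper_magnitude: float = 8.0
    # sessions
    arrival_rate: float = 20.0
    arrival_cv: float = 0.65
    group_p: float = 0.7
    group_max: int = 10
    p_separate: float = 0.5
    p_below_height: float = 0.03
    session_start_date: dt.date = dt.date(2022, 7, 21)
    sessions_per_day: int = 5

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_counters < 1:
            raise ValueError("n_counters must be >= 1")
        if len(self.base_rates) < self.n_counters:
            raise ValueError("base_rates must cover every counter")
        if any(r <= 0 for r in self.base_rates):
            raise ValueError("base_rates must be > 0")
        if len(self.weekday_effects) != 7 or any(w <= 0 for w in self.weekday_effects):
            raise ValueError("weekday_effects must be 7 positive multipliers")
        if len(self.season_effects) != 4 or any(s <= 0 for s in self.season_effects):
            raise ValueError("season_effects must be 4 positive multipliers")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("holiday_multiplier", "event_multiplier", "arrival_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_missing_day", "p_separate", "p_below_height", "group_p"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.group_p == 0.0:
            raise ValueError("group_p must be > 0")
        if self.arrival_cv < 0:
            raise ValueError("arrival_cv must be >= 0")
        if self.group_max < 1:
            raise ValueError("group_max must be >= 1")
        if self.n_events < 0 or self.n_tamper_spikes < 0:
            raise ValueError("event/tamper counts must be >= 0")

    @classmethod
    def zero_noise(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Counts are a pure function of weekday and season: no count
        noise, no weather effect, no holidays/events/tamper/missing."""
        cfg = cls(seed=seed,
                  deterministic_counts=True,
                  weather_betas=(0.0, 0.0, 0.0),
                  holiday_multiplier=1.0,
                  n_events=0,
                  p_missing_day=0.0,
                  n_tamper_spikes=0)
        return replace(cfg, **overrides) if overrides else cfg


_SEASON_INDEX = {Season.SPRING: 0, Season.SUMMER: 1,
                 Season.AUTUMN: 2, Season.WINTER: 3}


@dataclass
class SimTruth:
    """Ground truth of a simulated year, for recovery tests."""

    dates: list[dt.date]
    holidays: list[dt.date]
    events: list[dt.date]
    tamper: dict[str, list[dt.date]]
    missing: dict[str, list[dt.date]]
    rates: dict[str, np.ndarray]  # latent daily mean (post holiday/event effects)


@dataclass
class SessionTruth:
    """Per-group register: (above-height size, sensor registrations)."""

    groups: dict[tuple[str, str], list[tuple[int, int]]] = field(default_factory=dict)
    singles: dict[tuple[str, str], int] = field(default_factory=dict)


@dataclass
class SimulatedYear:
    series: list[CounterSeries]
    weather: list[WeatherDay]
    calendar: EventCalendar
    truth: SimTruth


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_weather(dates: list[dt.date], rng: np.random.Generator) -> list[WeatherDay]:
    out = []
    for date in dates:
        clim = WEATHER_CLIMATE[assign_season(date)[0]]
        temp = rng.normal(*clim["temp"])
        wet = rng.random() < _RAIN_WET_PROB
        rain = rng.exponential(clim["rain"] / _RAIN_WET_PROB) if wet else 0.0
        wind = max(rng.normal(*clim["wind"]), 0.0)
        out.append(WeatherDay(date, float(temp), float(rain), float(wind)))
    return out


def simulate_daily_counts(config: SimConfig) -> SimulatedYear:
    """Generate a monitoring year for every counter, plus weather,
    calendar and ground truth.  Fully reproducible from ``config.seed``."""
    config.validate()
    rng_weather, rng_event, rng_count, rng_tamper, rng_missing = _streams(
        config.seed, 5)

    dates = [config.start_date + dt.timedelta(days=i) for i in range(config.n_days)]
    date_index = {d: i for i, d in enumerate(dates)}
    weather = _simulate_weather(dates, rng_weather)

    holidays = [d for d in config.holidays if d in date_index]
    candidates = [d for d in dates if d not in holidays]
    n_events = min(config.n_events, len(candidates))
    events = sorted(rng_event.choice(len(candidates), size=n_events, replace=False).tolist())
    events = [candidates[i] for i in events]
    event_set, holiday_set = set(events), set(holidays)

    bt, br, bw = config.weather_betas
    log_weather = np.array([bt * (w.temp_c - 12.0) + br * w.rain_in
                            + bw * (w.wind_mph - 2.5) for w in weather])
    weekday_idx = np.array([d.weekday() for d in dates])
    season_idx = np.array([_SEASON_INDEX[assign_season(d)[0]] for d in dates])

    series_list = []
    truth = SimTruth(dates=dates, holidays=holidays, events=events,
                     tamper={}, missing={}, rates={})
    counter_ids = [f"counter_{i + 1}" for i in range(config.n_counters)]

    for ci, cid in enumerate(counter_ids):
        mu = (config.base_rates[ci]
              * np.asarray(config.weekday_effects)[weekday_idx]
              * np.asarray(config.season_effects)[season_idx]
              * np.exp(log_weather))
        for d in holidays:
            mu[date_index[d]] *= config.holiday_multiplier
        if ci in config.event_counters:
            for d in events:
                mu[date_index[d]] *= config.event_multiplier
        truth.rates[cid] = mu.copy()

        if config.deterministic_counts:
            totals = np.rint(mu).astype(np.int64)
        elif config.dispersion <= 0:
            totals = rng_count.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            totals = rng_count.negative_binomial(r, r / (r + mu))

        # tamper spikes: far above the outlier fence, on plain days only
        tamper_dates: list[dt.date] = []
        if config.n_tamper_spikes > 0:
            q1, q3 = np.quantile(totals, [0.25, 0.75])
            iqr = max(q3 - q1, 1.0)
            spike_value = int(math.ceil(q3 + config.tamper_magnitude * iqr))
            plain = [i for i, d in enumerate(dates)
                     if d not in holiday_set and d not in event_set]
            picks = rng_tamper.choice(len(plain), size=min(config.n_tamper_spikes,
                                                           len(plain)), replace=False)
            for p in sorted(picks.tolist()):
                i = plain[p]
                totals[i] = spike_value
                tamper_dates.append(dates[i])
        truth.tamper[cid] = tamper_dates

        missing_mask = rng_missing.random(config.n_days) < config.p_missing_day
        truth.missing[cid] = [d for d, m in zip(dates, missing_mask) if m]

        records = []
        for i, date in enumerate(dates):
            if missing_mask[i]:
                records.append(DailyCount(cid, date, None, None, missing=True))
            else:
                a = int(rng_count.binomial(int(totals[i]), 0.5))
                records.append(DailyCount(cid, date, a, int(totals[i]) - a))
        series_list.append(CounterSeries(cid, records))

    calendar = EventCalendar(
        holidays=frozenset(holidays), events=frozenset(events),
        labels={(d, "holiday"): "public holiday" for d in holidays}
        | {(d, "event"): "site event" for d in events},
    )
    return SimulatedYear(series_list, weather, calendar, truth)


# ---------------------------------------------------------------------------
# Observation sessions (occlusion model)


def group_size_pmf(config: SimConfig) -> np.ndarray:
    """PMF of group-unit size on {1..group_max}: geometric(p) truncated
    and renormalised."""
    g = np.arange(1, config.group_max + 1)
    pmf = config.group_p * (1.0 - config.group_p) ** (g - 1)
    return pmf / pmf.sum()


def _above_height_pmf(config: SimConfig) -> np.ndarray:
    """PMF of the above-beam-height size of a unit (binomial thinning)."""
    pmf_g = group_size_pmf(config)
    pa = np.zeros(config.group_max + 1)
    for g, pg in enumerate(pmf_g, start=1):
        for a in range(g + 1):
            pa[a] += pg * stats.binom.pmf(a, g, 1.0 - config.p_below_height)
    return pa


def expected_group_undercount(config: SimConfig) -> float:
    """E[undercount per *group*] = E[ga − 1 | ga >= 2] * (1 − p_separate).

    ``ga`` is a unit's above-height size; units with ga <= 1 are counted
    perfectly, so this is exactly the (negated) slope that the validity
    battery's group-effect regression estimates.
    """
    pa = _above_height_pmf(config)
    a = np.arange(pa.size)
    grp = a >= 2
    mean_excess = float(((a[grp] - 1) * pa[grp]).sum() / pa[grp].sum())
    return mean_excess * (1.0 - config.p_separate)


def expected_manual_rate(config: SimConfig) -> float:
    """Expected manual count per directional data point (per hour)."""
    pa = _above_height_pmf(config)
    return config.arrival_rate * float((np.arange(pa.size) * pa).sum())


def simulate_sessions(config: SimConfig, n_sessions: int,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[ObservationSession], SessionTruth]:
    """Generate paired one-hour sessions (two directional points each)."""
    config.validate()
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])

    pmf = group_size_pmf(config)
    sizes_support = np.arange(1, config.group_max + 1)

    sessions = []
    truth = SessionTruth()
    for i in range(n_sessions):
        sid = f"S{i + 1:02d}"
        date = config.session_start_date + dt.timedelta(days=i // config.sessions_per_day)
        hour = 8 + 2 * (i % config.sessions_per_day)
        if config.arrival_cv > 0:
            shape = 1.0 / config.arrival_cv ** 2
            busyness = float(rng.gamma(shape, 1.0 / shape))
        else:
            busyness = 1.0
        for direction in ("A", "B"):
            n_units = int(rng.poisson(config.arrival_rate * busyness))
            manual = sensor = below = n_groups = singles = 0
            register: list[tuple[int, int]] = []
            if n_units:
                sizes = rng.choice(sizes_support, size=n_units, p=pmf)
                for g in sizes:
                    bh = int(rng.binomial(g, config.p_below_height))
                    ga = int(g) - bh
                    below += bh
                    manual += ga
                    if ga == 0:
                        continue
                    registered = 1 + int(rng.binomial(ga - 1, config.p_separate))
                    sensor += registered
                    if ga >= 2:
                        n_groups += 1
                        register.append((ga, registered))
                    else:
                        singles += 1
            sessions.append(ObservationSession(
                session_id=sid, date=date, start_hour=hour, direction=direction,
                manual_count=manual, sensor_count=sensor,
                n_groups=n_groups, n_below_height=below))
            truth.groups[(sid, direction)] = register
            truth.singles[(sid, direction)] = singles
    return sessions, truth


def write_simulation(sim: SimulatedYear, outdir,
                     sessions: list[ObservationSession] | None = None) -> None:
    """Write the generated inputs in the CSV dialects `counts_io` reads,
    plus a ground-truth day-label CSV for test harnesses."""
    import pandas as pd

    from . import counts_io
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_io.write_daily_counts(sim.series, outdir / "counts.csv")
    counts_io.write_weather(sim.weather, outdir / "weather.csv")
    counts_io.write_calendar(sim.calendar, outdir / "calendar.csv")
    rows = []
    for kind, dates in (("holiday", sim.truth.holidays), ("event", sim.truth.events)):
        rows += [{"counter_id": "", "date": d.isoformat(), "label": kind} for d in dates]
    for cid, dates in sim.truth.tamper.items():
        rows += [{"counter_id": cid, "date": d.isoformat(), "label": "tamper"} for d in dates]
    for cid, dates in sim.truth.missing.items():
        rows += [{"counter_id": cid, "date": d.isoformat(), "label": "missing"} for d in dates]
    pd.DataFrame(rows, columns=["counter_id", "date", "label"]).to_csv(
        outdir / "truth_days.csv", index=False)
    if sessions is not None:
        counts_io.write_sessions(sessions, outdir / "sessions.csv")
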