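"""Validity battery for paired one-hour manual vs sensor counts.

Each observation session contributes two directional data points
(direction A and B counted separately), so a ten-session battery yields
twenty points.  The battery reproduces the standard agreement workflow
for an automated counter validated against direct observation:

* Bland–Altman analysis of sensor − manual differences (systematic
  bias, limits of agreement, MAPE, percentage difference);
* proportional-bias regression of differences on pair means;
* group-effect regression of differences on the number of groups that
  passed through the counter (groups occlude the infrared beam, so more
  groups should mean a larger undercount);
* concurrent-validity regression of manual counts on sensor counts
  (sensor as predictor; with undercounting the slope exceeds 1).

People below the beam height are tallied per session but excluded from
every statistic, since the target of validation is the sensor's true
counts rather than total path footfall.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np

from .agreement import (BlandAltmanResult, RegressionResult, bland_altman,
                        ols_fit, proportional_bias)

__all__ = [
    "ObservationSession",
    "SessionDescriptives",
    "ValidityReport",
    "run_validity",
    "session_descriptives",
]


@dataclass(frozen=True)
class ObservationSession:
    """One directional data point from a one-hour paired observation."""

    session_id: str
    date: dt.date
    start_hour: int
    direction: str  # "A" or "B"
    manual_count: int  # people >= beam height counted by the observer
    sensor_count: int  # beam-break registrations
    n_groups: int  # groups (>= 2 people at beam height) passing through
    n_below_height: int  # recorded but excluded from analysis

    def __post_init__(self) -> None:
        if min(self.manual_count, self.sensor_count,
               self.n_groups, self.n_below_height) < 0:
            raise ValueError(f"{self.session_id}/{self.direction}: negative count")
        if self.direction not in ("A", "B"):
            raise ValueError(f"{self.session_id}: direction must be 'A' or 'B'")


@dataclass(frozen=True)
class SessionDescriptives:
    n_points: int
    n_sessions: int
    manual_mean: float
    manual_sd: float
    manual_min: int
    manual_max: int
    sensor_mean: float
    sensor_sd: float
    sensor_min: int
    sensor_max: int
    groups_min: int
    groups_max: int


@dataclass(frozen=True)
class ValidityReport:
    """All validity statistics, computed on the same directional points."""

    agreement: BlandAltmanResult
    proportional_bias: RegressionResult
    group_effect: RegressionResult
    concurrent: RegressionResult
    descriptives: SessionDescriptives


def session_descriptives(sessions: list[ObservationSession]) -> SessionDescriptives:
    """Per-method means/SDs and ranges; SD is NaN for a single point."""
    if not sessions:
        raise ValueError("no sessions supplied")
    manual = np.array([s.manual_count for s in sessions], dtype=float)
    sensor = np.array([s.sensor_count for s in sessions], dtype=float)
    groups = np.array([s.n_groups for s in sessions])
    sd = (lambda v: float(np.std(v, ddof=1)) if v.size > 1 else math.nan)
    return SessionDescriptives(
        n_points=len(sessions),
        n_sessions=len({s.session_id for s in sessions}),
        manual_mean=float(manual.mean()), manual_sd=sd(manual),
        manual_min=int(manual.min()), manual_max=int(manual.max()),
        sensor_mean=float(sensor.mean()), sensor_sd=sd(sensor),
        sensor_min=int(sensor.min()), sensor_max=int(sensor.max()),
        groups_min=int(groups.min()), groups_max=int(groups.max()),
    )


def run_validity(sessions: list[ObservationSession]) -> ValidityReport:
    """Run the full agreement battery on directional data points."""
    if len(sessions) < 3:
        raise ValueError(f"need >= 3 directional points, got {len(sessions)}")
    sensor = np.array([s.sensor_count for s in sessions], dtype=float)
    manual = np.array([s.manual_count for s in sessions], dtype=float)
    groups = np.array([s.n_groups for s in sessions], dtype=float)
    diff = sensor - manual
    return ValidityReport(
        agreement=bland_altman(sensor, manual),
        proportional_bias=proportional_bias(sensor, manual),
        group_effect=ols_fit(groups, diff),
        concurrent=ols_fit(sensor, manual),
        descriptives=session_descriptives(sessions),
    )
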