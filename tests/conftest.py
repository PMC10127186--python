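import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import footfall as ff

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_series(counter_id="c1", start=dt.date(2021, 9, 1), totals=None,
                missing_dates=()):
    """Contiguous CounterSeries with given daily totals (split 60/40)."""
    records = []
    missing_dates = set(missing_dates)
    for i, total in enumerate(totals):
        date = start + dt.timedelta(days=i)
        if date in missing_dates or total is None:
            records.append(ff.DailyCount(counter_id, date, None, None, missing=True))
        else:
            a = int(total) * 3 // 5
            records.append(ff.DailyCount(counter_id, date, a, int(total) - a))
    return ff.CounterSeries(counter_id, records)


@pytest.fixture
def autumn_series():
    """A clean 91-day autumn (2021-09-01 .. 2021-11-30): 13 full weeks."""
    rng = np.random.default_rng(7)
    totals = rng.poisson(200, size=91)
    return make_series(totals=totals)


@pytest.fixture
def empty_calendar():
    return ff.EventCalendar(frozenset(), frozenset())
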