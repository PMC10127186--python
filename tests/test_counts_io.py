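"""I/O, season assignment and week layout."""

import datetime as dt
import textwrap

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import footfall as ff
from footfall.counts_io import Season, format_weather_summary

from conftest import make_series


@pytest.mark.parametrize("date, season, year", [
    (dt.date(2021, 6, 15), Season.SUMMER, "2021"),
    (dt.date(2022, 1, 10), Season.WINTER, "2021"),
    (dt.date(2021, 11, 30), Season.AUTUMN, "2021"),
    (dt.date(2021, 12, 1), Season.WINTER, "2021"),
    (dt.date(2021, 3, 1), Season.SPRING, "2021"),
    (dt.date(2021, 5, 31), Season.SPRING, "2021"),
    (dt.date(2020, 2, 29), Season.WINTER, "2019"),
])
def test_assign_season(date, season, year):
    assert ff.assign_season(date) == (season, year)


@given(st.dates(min_value=dt.date(1990, 1, 1), max_value=dt.date(2050, 12, 31)))
def test_every_day_maps_to_one_season(date):
    season, year = ff.assign_season(date)
    assert season in list(Season)
    assert year.isdigit()


def test_year_partitions_into_seasons():
    days = [dt.date(2021, 1, 1) + dt.timedelta(days=i) for i in range(365)]
    counts = {s: 0 for s in Season}
    for d in days:
        counts[ff.assign_season(d)[0]] += 1
    assert sum(counts.values()) == 365
    assert counts[Season.SPRING] == 92 and counts[Season.SUMMER] == 92
    assert counts[Season.AUTUMN] == 91 and counts[Season.WINTER] == 90


def write(tmp_path, text):
    p = tmp_path / "counts.csv"
    p.write_text(textwrap.dedent(text))
    return p


class TestReadDailyCounts:
    def test_contiguous(self, tmp_path):
        p = write(tmp_path, """\
            counter_id,date,count_a,count_b
            c1,2021-06-01,5,7
            c1,2021-06-02,4,4
            c1,2021-06-03,0,1
        """)
        (series,) = ff.read_daily_counts(p)
        assert len(series) == 3
        assert not any(r.missing for r in series.records)
        assert series.records[0].total == 12

    def test_gap_materialised_as_missing(self, tmp_path):
        p = write(tmp_path, """\
            counter_id,date,count_a,count_b
            c1,2021-06-01,5,7
            c1,2021-06-03,4,4
        """)
        (series,) = ff.read_daily_counts(p)
        assert len(series) == 3
        gap = series.records[1]
        assert gap.date == dt.date(2021, 6, 2) and gap.missing and gap.total is None

    def test_malformed_date_names_line(self, tmp_path):
        p = write(tmp_path, """\
            counter_id,date,count_a,count_b
            c1,2021-06-01,5,7
            c1,junk,4,4
        """)
        with pytest.raises(ValueError, match="line 3"):
            ff.read_daily_counts(p)

    def test_negative_count_rejected(self, tmp_path):
        p = write(tmp_path, """\
            counter_id,date,count_a,count_b
            c1,2021-06-01,-5,7
        """)
        with pytest.raises(ValueError, match="negative"):
            ff.read_daily_counts(p)

    def test_duplicate_date_rejected(self, tmp_path):
        p = write(tmp_path, """\
            counter_id,date,count_a,count_b
            c1,2021-06-01,5,7
            c1,2021-06-01,4,4
        """)
        with pytest.raises(ValueError, match="duplicate"):
            ff.read_daily_counts(p)


@given(st.lists(st.one_of(st.none(), st.integers(0, 500)), min_size=1, max_size=40),
       st.dates(min_value=dt.date(2020, 1, 1), max_value=dt.date(2023, 1, 1)))
def test_roundtrip_write_read(tmp_path_factory, totals, start):
    # interior missing days survive; trim edges so the monitored range is stable
    if totals[0] is None:
        totals[0] = 1
    if totals[-1] is None:
        totals[-1] = 1
    series = make_series(start=start, totals=totals)
    path = tmp_path_factory.mktemp("rt") / "counts.csv"
    ff.write_daily_counts([series], path)
    (back,) = ff.read_daily_counts(path)
    assert back.counter_id == series.counter_id
    assert back.records == series.records


class TestLayoutSeason:
    def test_91_clean_days_give_13_complete_weeks(self, autumn_series):
        layout = ff.layout_season(autumn_series, Season.AUTUMN)
        assert layout.n_weeks == 13
        assert layout.complete_weeks == list(range(13))
        assert layout.remainder == []
        assert all(len(w) == 7 for w in layout.weeks)

    def test_missing_day_breaks_its_week_only(self):
        series = make_series(totals=[200] * 91,
                             missing_dates={dt.date(2021, 9, 1) + dt.timedelta(days=24)})
        layout = ff.layout_season(series, Season.AUTUMN)
        assert layout.n_weeks == 13
        assert len(layout.complete_weeks) == 12
        assert 3 not in layout.complete_weeks  # day 24 falls in block 4

    def test_87_days_truncated_layout(self):
        series = make_series(totals=[100] * 87)
        layout = ff.layout_season(series, Season.AUTUMN)
        # brute-force: 87 // 7 = 12 blocks, 3 remainder days
        assert layout.n_weeks == 12
        assert len(layout.remainder) == 3
        assert len(layout.complete_weeks) == 12

    def test_week_lengths_plus_remainder_cover_season(self, autumn_series):
        layout = ff.layout_season(autumn_series, Season.AUTUMN)
        total = sum(len(w) for w in layout.weeks) + len(layout.remainder)
        assert total == len(autumn_series)

    def test_season_pooled_across_year_wrap(self):
        # monitoring 2021-05-04 .. 2022-05-03: spring has two segments
        sim = ff.simulate_daily_counts(ff.SimConfig.zero_noise(seed=0, n_counters=1))
        layout = ff.layout_season(sim.series[0], Season.SPRING)
        assert layout.n_weeks == 13
        assert len(layout.remainder) == 1  # 92 spring days
        assert layout.year_label == "2021/2022"
        # every block covers all seven weekdays exactly once
        for week in layout.weeks:
            assert len({r.date.weekday() for r in week}) == 7

    def test_empty_overlap_errors(self, autumn_series):
        with pytest.raises(ValueError, match="no monitored days"):
            ff.layout_season(autumn_series, Season.SPRING)


class TestWeatherSummary:
    def test_constant_series(self):
        days = [ff.WeatherDay(dt.date(2021, 6, 1) + dt.timedelta(days=i), 10.0, 0.0, 1.0)
                for i in range(5)]
        s = ff.weather_summary(days)
        assert s.loc["Summer", ("temp_c", "mean")] == 10.0
        assert s.loc["Summer", ("temp_c", "std")] == 0.0
        assert s.loc["Summer", ("temp_c", "min")] == s.loc["Summer", ("temp_c", "max")] == 10.0

    def test_two_day_sample_sd(self):
        days = [ff.WeatherDay(dt.date(2021, 6, 1), 8.0, 0.0, 1.0),
                ff.WeatherDay(dt.date(2021, 6, 2), 12.0, 0.0, 1.0)]
        s = ff.weather_summary(days)
        assert s.loc["Summer", ("temp_c", "mean")] == pytest.approx(10.0)
        assert s.loc["Summer", ("temp_c", "std")] == pytest.approx(2.8284, abs=1e-4)
        formatted = format_weather_summary(s)
        assert "8" in formatted.loc["Summer", "temp_c"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ff.weather_summary([])

    def test_generator_roundtrip_summer_mean(self):
        sim = ff.simulate_daily_counts(ff.SimConfig(seed=11, n_counters=1))
        s = ff.weather_summary(sim.weather)
        n = 92
        assert s.loc["Summer", ("temp_c", "mean")] == pytest.approx(
            17.5, abs=4 * 2.39 / np.sqrt(n))
        assert s.loc["Winter", ("temp_c", "mean")] == pytest.approx(
            6.64, abs=4 * 2.97 / np.sqrt(90))
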