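# footfall

Reliability and validity analysis for **automated active infrared footfall
counters** on park and trail footpaths.

Active infrared counters (a transmitter/receiver gate across a path)
register a count whenever their beam is broken. They are cheap and
unobtrusive, which makes them attractive for physical-activity
surveillance and natural-experiment evaluations of greenspace
interventions — but two questions decide whether their numbers can be
trusted:

1. **Behavioural stability.** How many weeks of monitoring per
   meteorological season (Spring, Summer, Autumn, Winter) are needed
   before an abbreviated schedule's estimate of daily footfall is
   consistent with the full season?
2. **Validity.** How do sensor counts compare with direct manual
   observation? Beam counters cannot resolve several people crossing
   simultaneously, so groups cause systematic undercounting.

This package implements both analyses as a tested pipeline, driven
either by real counter CSV exports or by a bundled synthetic-data
generator with known ground truth.

## What it computes

**Screening.** Daily totals are screened per counter with a 3 × IQR
extreme-outlier rule (fences at Q1 − 3·IQR and Q3 + 3·IQR on the full
monitored series). Public holidays are excluded for every counter;
site-event days are excluded only for counters that spiked on them;
remaining outliers are excluded as unexplained.

**Stability.** Each season is laid out as up to 13 consecutive 7-day
weeks anchored at the first monitored day. For every schedule length
*k* ∈ {1..4} the pipeline enumerates all C(m, k) subsets of the m
complete weeks, summarises each subset as a weekday (Mon–Sun) median
profile, and scores it against the full-season profile with the
two-way mixed, single-measure, *consistency* intraclass correlation

ICC(C,1) = (MS_rows − MS_err) / (MS_rows + (k_raters − 1)·MS_err),

with a 95% CI from the F ratio MS_rows/MS_err. Per-combination ICCs are
averaged into a stability table with interpretation bands
(<0.5 poor, 0.5–0.75 moderate, >0.75 good, >0.9 excellent).

**Validity.** Paired one-hour manual/sensor sessions (two directional
data points per session) are analysed with a Bland–Altman battery:
mean difference (sensor − manual) with 1.96·SD limits of agreement, a
one-sample t-test for systematic bias, MAPE and percentage difference,
a proportional-bias regression (differences on pair means), a
group-effect regression (differences on the number of groups) and a
concurrent-validity regression (manual on sensor counts).

**Simulation.** The generator produces a negative-binomial daily count
model with weekday, season and weather effects, holiday/event spikes,
tamper outliers and missing days — plus an occlusion model of
observation sessions in which each group's first member always breaks
the beam and later members register independently. Ground truth is
returned for recovery tests.

## Worked example

```python
import footfall as ff

cfg = ff.SimConfig(seed=42)                      # a simulated monitoring year
sim = ff.simulate_daily_counts(cfg)
for r in ff.screen_counters(sim.series, sim.calendar):
    print(f"{r.counter_id}: retained {r.retained_days} days, excluded {r.excluded_days}")

table = ff.stability_table(sim.series)
print(table[(table.counter_id == "counter_1") & (table.season == "Autumn")]
      [["k_weeks", "mean_icc", "ci_low", "ci_high", "n_combinations", "band"]]
      .round(2).to_string(index=False))

sessions, _ = ff.simulate_sessions(cfg, 10)      # 10 sessions = 20 points
rep = ff.run_validity(sessions)
ba = rep.agreement
print(f"mean diff {ba.mean_diff:.2f} counts/h "
      f"(LoA {ba.loa_low:.2f}, {ba.loa_high:.2f}; MAPE {ba.mape:.1f}%)")
print(f"concurrent: beta {rep.concurrent.slope:.2f}, r2 {rep.concurrent.r_squared:.2f}")
print(f"group effect: slope {rep.group_effect.slope:.2f}, r2 {rep.group_effect.r_squared:.2f}")
```

prints

```
counter_1: retained 347 days, excluded 12
counter_2: retained 353 days, excluded 11
counter_3: retained 352 days, excluded 11
 k_weeks  mean_icc  ci_low  ci_high  n_combinations     band
       1      0.31   -0.47     0.82              10     poor
       2      0.52   -0.23     0.89              45 moderate
       3      0.50   -0.26     0.88             120     poor
       4      0.62   -0.10     0.92             210 moderate
mean diff -6.00 counts/h (LoA -16.25, 4.25; MAPE 15.8%)
concurrent: beta 1.17, r2 0.99
group effect: slope -0.68, r2 0.81
```

Reading it: screening dropped ~11–12 counter-days (holidays, event
spikes and injected tamper outliers). For counter 1's autumn, one-week
schedules agree poorly with the full season (mean ICC 0.31) while
four-week schedules reach moderate consistency over all 210 possible
4-of-10 week choices — longer schedules track the season better. The
sensor undercounts by 6 counts/h on average (it can only undercount:
groups occlude the beam), undercounting grows with the number of
groups (negative slope, r² 0.81), yet sensor counts still explain 99%
of the variance in manual counts with a slope above 1.

The same stages are available from a shell:

```sh
footfall simulate --seed 42 --out data/
footfall screen --counts data/counts.csv --calendar data/calendar.csv --out exclusions.csv
footfall stability --counts data/counts.csv --calendar data/calendar.csv --out table.csv
footfall validity --sessions data/sessions.csv --out report.csv --plots figs/
```

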