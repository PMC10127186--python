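# Methods

This note documents the statistical model behind each pipeline stage,
the defaults and units of the tunable parameters, the design decisions
taken where the methodology was genuinely open, and the limits of what
the synthetic tests demonstrate.

## Data model and season layout

A counter-day is a pair of non-negative directional beam-break counts;
their sum is the daily footfall total used throughout. Missing days
are materialised explicitly (a day inside the monitored range with no
row, or a row with blank counts) and never enter any statistic.

Meteorological seasons are whole three-month blocks (Mar–May, Jun–Aug,
Sep–Nov, Dec–Feb); Winter is labelled with the year of its December. A
monitoring year that starts mid-season contributes two segments of the
same season (e.g. late spring at the start and early spring at the
end); the pipeline pools them chronologically.

Within a season, candidate weeks are consecutive 7-day blocks anchored
at the **first monitored day** of the season, not at ISO week
boundaries — a monitoring campaign rarely starts on a Monday or on the
first of a month, and anchoring at the start yields exactly 13 blocks
for a 91/92-day season. Days beyond 13 × 7 belong to the season (they
enter season-level medians and profiles) but to no week. A week is
*complete* when all 7 of its days are retained after screening and the
block covers all seven weekdays; only complete weeks can enter an
abbreviated schedule. With a mid-week anchor every block still covers
each weekday exactly once, so weekday profiles are always balanced.

## Screening

Extreme outliers are daily totals strictly outside
[Q1 − 3·IQR, Q3 + 3·IQR], with quartiles computed once on the full
pre-exclusion non-missing series using the linear-interpolation
quantile definition (the common statistical default; the screening
rule itself does not prescribe one). Screening is single-pass — the
fences are not recomputed after removals — which makes it idempotent,
and raising the multiplier can only shrink the flagged set. Both
fences are checked even though field tampering and events inflate
counts; low-side outliers are flagged identically.

Calendar rules are deliberately asymmetric: public holidays are
removed for every counter whether or not they spiked (holiday footfall
is systematically atypical), while site-event days are removed only
for counters that registered an extreme outlier that day (an event at
one end of a park need not disturb a counter at the other). A date
that is both holiday and event counts as holiday. Whatever remains
flagged is excluded as an unexplained outlier (tampering, foliage).

## Stability analysis

The estimand is the consistency between an abbreviated schedule's
picture of a season and the full season's. Each candidate schedule
(a k-week subset, k = 1..4, enumerated exhaustively over the season's
complete weeks — C(13, k) = 13, 78, 286, 715 subsets when all 13 weeks
are complete) is summarised as its weekday median profile: the median
daily total for each of Monday..Sunday over the subset's days. The
full-season reference profile uses every retained day of the season.

Each subset is scored with ICC(C,1) on the 7 × 2 matrix whose rows are
weekdays and whose columns are the two schedules. The consistency form
is the right one here: an abbreviated schedule that reproduces the
season's day-of-week *structure* but sits at a different level (a
sunnier fortnight, say) should still score highly, and ICC(C,1) is
invariant to a constant column offset. The week-subset × full-season
pairing is the one genuinely open methodological choice in this
design; it is implemented behind `score_combination`, which accepts
any pair of 7-vectors, so an alternative pairing can be swapped in.
The reference profile includes the subset's own weeks (the comparison
is against the *entire* season, not the complement).

ICC(C,1) is computed from the two-way ANOVA decomposition,
`(MS_rows − MS_err) / (MS_rows + (k_raters − 1)·MS_err)`, with the
95% CI obtained from F = MS_rows/MS_err with (n−1) and (n−1)(k−1)
degrees of freedom. With 7 subjects and 2 raters those CIs are wide by
construction. When MS_err is numerically zero relative to MS_rows
(identical or constant-shifted columns) the ICC is exactly 1; a matrix
with no variance at all has an undefined ICC and is flagged, and such
degenerate combinations drop out of cell aggregates.

Per cell (counter × season × k) the table reports the mean of the
per-combination ICCs and, by default, the mean of the per-combination
F-based CI bounds; an alternative empirical CI (2.5th/97.5th
percentiles of the combination ICCs) is available via
`ci_method="percentile"`, since no single aggregation of
per-combination intervals is canonical. Bands: <0.5 poor, 0.5–0.75
moderate, (0.75, 0.9] good, >0.9 excellent; the half-open boundary at
0.75 follows the "good = ICC > 0.75" convention.

No weather adjustment is made in the stability analysis: weather is
strongly collinear with season, and the per-season stratification is
the adjustment.

## Validity battery

Sessions are one-hour paired observations; the two directions of
travel are separate data points. All statistics are oriented
sensor − manual, so an occlusion-limited sensor produces negative
bias. Limits of agreement are mean ± 1.96·SD with the sample
(n−1) SD and the literal 1.96 normal quantile. The one-sample t-test
of the differences against zero is two-sided. MAPE averages
100·|diff|/manual over points with a nonzero manual count;
zero-reference points are dropped and counted. Percentage difference
is 100·mean_diff / mean(manual). The group-effect regression uses the
number of groups per directional point as predictor; the concurrent
regression predicts manual from sensor counts, so undercounting shows
up as a slope above 1. People below beam height are recorded per
session but enter no statistic: the validation target is what the
sensor could in principle see.

## Synthetic-data generator

The generator is the package's test bed: it produces all four inputs
with the structure the analyses assume, plus ground truth.

Daily counts: `mu = base · weekday_effect · season_effect ·
exp(β_t (T − 12°C) + β_r rain + β_w (wind − 2.5 mph))`, with totals
negative-binomial (variance mu + φ·mu²) and a 50/50 binomial direction
split. Defaults: base rates (225, 115, 85) counts/day spanning a busy
paved path to a quiet woodland path; weekday multipliers
(0.92, 0.90, 0.95, 0.97, 1.05, 1.30, 1.20) Mon..Sun (weekends busier);
season multipliers (1.05, 1.30, 1.00, 0.85) for Spring/Summer/Autumn/
Winter; weather betas (0.012 /°C, −0.8 /inch, −0.02 /mph); φ = 0.06.
Weather is drawn per season around the observed climatology of an
English urban park year (e.g. Summer 17.5 ± 2.39 °C, Winter
6.64 ± 2.97 °C; rainfall zero-inflated exponential; wind truncated
normal). Holidays (England bank holidays of the simulated year)
multiply the rate by 2.2 everywhere; events (4 random days) by 3.0 on
the event-affected counters only (default: counter 1); tamper spikes
replace a day's count with ⌈Q3 + 8·IQR⌉, well outside the 3×IQR fence,
so an unmasked screen must recall them completely; days go missing
independently with p = 0.01. `SimConfig.zero_noise()` switches off
every noise source, making counts a pure function of weekday and
season — on that input every stability cell must be exactly 1.

Sessions: group-units arrive Poisson with 20 units/h per direction,
scaled by a per-session gamma busy-ness multiplier (CV 0.65, shared by
both directions) because hourly park footfall varies severalfold over
a day; unit size is truncated-geometric (p = 0.7, max 10; mean ≈ 1.43);
each member is below beam height with p = 0.03; the first above-height
member always registers and each further member registers with
p_separate = 0.5. Sensor ≤ manual holds for every simulated session
(pure occlusion). The implied analytic group-effect slope is
−E[ga − 1 | ga ≥ 2]·(1 − p_separate) where ga is a unit's above-height
size (`expected_group_undercount`); the validity battery's regression
estimate converges to it, which the recovery tests exploit. These
defaults give a manual mean near 28 counts/h and an undercount near
16% of the manual mean.

What the generator does **not** emulate: day-to-day weather
autocorrelation, directional asymmetry, sensor overcounting (foliage,
animals, deliberate beam-waving beyond the injected spike days),
drift/misalignment, or arrival-rate seasonality within sessions.
Passing recovery tests therefore demonstrate that the pipeline
estimates what the occlusion/count model encodes — not that a
particular field deployment will show the same numbers.

## Numerical and testing choices

* Sample (n−1) standard deviations wherever descriptives are reported;
  medians use the midpoint convention for even counts.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawns, so every output is reproducible
  and per-module streams are independent.
* Degenerate inputs fail loudly (too few values to screen, a weekday
  with no retained days, zero-variance predictors) rather than
  returning silent NaNs, except where a flagged NaN is the documented
  contract (undefined ICC, undefined MAPE).
* The stability recovery test averages 50 simulated years and allows a
  0.01 slack on the monotonicity of mean ICC in k, reflecting sampling
  error of a Monte-Carlo mean; the validity recovery test compares the
  mean of 100 battery slopes to the analytic slope within two standard
  errors. Problem sizes (one counter for the multi-seed stability
  sweep; 10-session batteries, matching the design being emulated)
  keep the whole suite near half a minute while leaving the Monte-
  Carlo error far below the tested effects.

## Known limitations

* The week-subset × season ICC pairing is a documented interpretive
  choice (see above); other pairings (e.g. day-level pairings or
  leave-subset-out references) would change the absolute ICC scale.
* The F-based CI aggregation across combinations is a mean of
  dependent intervals and has no exact coverage guarantee; the
  percentile alternative is provided.
* Screening fixes quartiles on the pre-exclusion series by design; a
  heavily contaminated series (many spikes) would widen the fences and
  could mask lesser spikes.
* Field data with sensor overcounting violates the occlusion model's
  sensor ≤ manual guarantee; the validity battery still runs, but the
  generator cannot emulate that regime.
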