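# Methods

This note documents the statistical procedures fjordlink implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions used throughout.

## Problem setting

Cabled shallow-water observatories in polar fjords record essential ocean
variables (water temperature, salinity) at high frequency year-round,
alongside weekly stereoscopic surveys of the macrofauna and fish
community.  Fjords at the Atlantic–Arctic boundary alternate between
warm-saline Atlantic-inflow phases and cold-fresh Arctic phases, which
manifest as marine heat waves, cold spells and salinity anomalies against
the seasonal cycle.  fjordlink asks whether such short-term hydrographic
anomalies, accumulated over a biological year, are coupled to anomalies in
community abundance.

## Daily aggregation

Raw samples are binned by UTC calendar date (the choice of timezone is a
convention; it is fixed and documented rather than configurable per run).
A daily mean is reported only when the fraction of expected samples
present (`coverage`) reaches `min_coverage` (default 0.5): a handful of
readings should not define a day.  The expected samples per day are
inferred from the median inter-sample interval unless given.  Unparseable
rows are logged with line numbers and the read continues; no
quality-control beyond finiteness is applied to raw values.

## Climatology

For each calendar day d (leap-aware 366-day axis, 29 February = unit 60;
no day is deleted), all non-missing values whose day-of-year lies within
±`window_halfwidth` days of d across all years are pooled.  The pool's
arithmetic mean gives the reference curve and its 10th/90th percentiles
the envelope (both fractions configurable).  All three curves may be
smoothed with a circular moving average (`smooth_span`), which preserves
each curve's global mean exactly.

Defaults follow the marine-heat-wave literature's standard recipe:
`window_halfwidth = 5` (an 11-day pooling window) and `smooth_span = 31`
days.  With under a decade of data the percentile estimator is material:
sorting with linear interpolation between order statistics is the default
and the estimator name is recorded in the table's metadata sidecar.
Weekly (biotic) climatologies use the cohort-anchored week-of-year keying
with `window_halfwidth` in weeks (default ±1) and no smoothing.

No detrending is applied before the climatology is built.

## Event detection

A heat wave (cold spell) is a run of at least `min_duration` consecutive
days with the daily value strictly above the upper (below the lower)
envelope; salinity anomalies use the identical machinery.  "At least five
consecutive days" is the default threshold, matching the canonical
marine-heat-wave definition; a stricter ≥ 6 reading is available by
setting `min_duration = 6`.  `max_gap` defaults to 0 (phases must be
continuous); a gap-joining mode (`max_gap = 2`) exists for sensitivity
analysis, in which same-sign runs separated by that many in-envelope,
non-missing days merge and gap days count toward the duration.  Missing
days always terminate runs and never count toward gaps.

Event intensity ("day-degrees", unit·days) is the sum over event days of
the daily exceedance relative to a baseline.  Because the baseline
convention is ambiguous in field usage, both are computed and exported:
the climatological mean (default, the usual intensity convention) and the
crossed percentile threshold.  The per-day "net anomalous value" is the
signed exceedance beyond the crossed envelope, reported only on event
days; its sum over one event equals that event's threshold-baseline
day-degrees.

## CPUE standardization and biotic anomalies

Weekly survey effort is nominally 336 stereoscopic image pairs
(2 images/hour × 24 h × 7 days).  CPUE = count × 336 / effort.  Weeks
with fewer than `effort_floor = 48` analysed pairs (one full day) are
marked missing rather than rescaled.  The weekly grid is anchored at
01 August of each cohort year so week boundaries align with cohort years;
weeks are assigned to months by their start date for the monthly
mean ± SD summaries (weeks as replicates; single-week months report a
missing SD by default).  The biotic detector mirrors the abiotic one at
weekly resolution with a one-week minimum duration — a seven-day sampling
unit is the finest the survey design supports, so the five-day abiotic
phase extends to one week.  "Jellyfish"/"scyphozoa", "fish"/"pisces" and
"decapoda"/"benthic crustacea" labels are unified through an alias table.

## Cohort-year aggregation and coupling statistics

The biological year at high latitudes runs from the polar summer through
the polar winter: cohort year Y spans 01 Aug Y – 31 Jul Y+1.  Events
straddling the boundary are split by day, conserving total day-degrees.
Per cohort and variable the positive, negative and net cumulative anomaly
sums are computed; the net sum is the default ranking key, ordering
cohorts on a single axis from the most anomalous cold spell (rank 1) to
the most anomalous heat wave (rank n).  Positive-only and negative-only
keys are available.

Cohort ranks are coupled by ordinary least squares of biotic ranks on
abiotic ranks.  For untied ranks the slope equals the Spearman rank
correlation, and for n = 8 cohorts reduces to slope = 1 − Σd²/84.  The
slope's F statistic has (1, n−2) degrees of freedom, equals t², and p is
two-sided; a perfect fit reports F = t = ∞ with p = 0 by convention, and
an all-tied response reports a null result (slope 0, p 1).  Group
exclusions (e.g. the without-jellyfish variant) rebuild the TOTAL weekly
CPUE from counts *before* anomaly detection — anomalies are nonlinear in
the climatological threshold, so subtracting a group's anomalies
afterwards would not be equivalent.  No multiple-testing correction is
applied across the per-group regressions; the regression table reports
raw two-sided p-values.

Mann–Kendall trend tests are run on the per-cohort anomaly frequency
(event counts) and intensity (cumulative |day-degrees|) series, one per
sign and variable.  S = Σ_{i<j} sign(x_j − x_i); tau is tie-corrected
(tau-b against the tie-free time axis).  For n ≤ 10 without ties the
two-sided p comes from the exact null distribution of S (computed from
the permutation inversion-count generating function); otherwise from the
tie-corrected normal approximation with continuity correction.

## Synthetic generator

The generator emulates the *structure* of a polar-fjord observatory
record, not the spectra of any specific fjord:

* **Abiotic:** daily value = seasonal sinusoid + AR(1) noise + injected
  boxcar events.  Defaults: temperature 3.0 ± 3.5 °C with maximum at
  day-of-year 220 (early August), salinity 34.0 ± 0.8 PSU peaking in late
  winter (day 50), AR(1) coefficient 0.7, noise SD 0.35 °C / 0.15 PSU.
  The noise scale is per-variable because the two units differ.  The
  sinusoid is evaluated on the same leap-aware calendar axis as the
  climatology, so with zero noise every year contributes an identical
  value per unit and the series' own envelope collapses onto it.
* **Biotic:** expected CPUE per group and week = winter-peaked raised-
  cosine seasonal profile × exp(β·z), where z is the standardized cohort
  net day-degree exposure from the injected-event ground truth and β
  (`coupling_beta`) is the coupling strength.  Counts are gamma-mixed
  Poisson (negative binomial; shape `dispersion = 5` gives realistic
  overdispersion for weekly macrofauna counts).  Effort is 336 image
  pairs, degraded to a uniform draw in [24, 335] with probability
  `effort_dropout = 0.1`, so some weeks fall below the effort floor and
  become missing — mimicking observatory outages.
* **Scenarios:** `demo_scenario` spans 8 cohort years and injects
  Poisson(2.5) temperature events per year (5–20 days, 1–3 °C) whose sign
  is biased by a per-year regime draw, mimicking the alternation between
  Atlantic (heat-wave-rich) and Arctic (cold-spell-rich) phases; this
  regime structure is what gives cohorts the between-year contrast the
  rank statistics need.  `zero_noise_scenario` places a few well-separated
  injections in distinct seasons so that, against a climatology built
  with `window_halfwidth = 0` and no smoothing, detection recovers the
  injected day-sets exactly.
* **Determinism:** one master seed is split into named substreams per
  variable and group, so adding a group never perturbs existing streams.

What passing the synthetic tests does **not** show: the generator has no
trends, no tides or storm-driven transients, no species-level structure
within groups, no observation error in classification, and its coupling
is by construction exactly the cohort-level mechanism the statistics
target.  Recovery results therefore validate the machinery, not the
ecological model.

## Problem sizes and numerical conventions

Simulation-based checks use 8-cohort-year scenarios (~2 900 daily values,
416 survey weeks): 100 seeds for the coupling sign-recovery rate and 500
seeds for the null false-positive calibration, which bounds the Monte
Carlo error of a 5% rate at about ±1 percentage point (1 SE).  Exceedance
comparisons are strict (`>` / `<`); envelope ties are therefore inside
the envelope.  Ranks use average-rank tie handling.  Floating-point
residual tests treat relative residual variance below 1e−12 as a perfect
fit.

## Known limitations

* The real observatories' quality-control rules for raw 1 Hz data are not
  reproduced; ingestion assumes pre-cleaned samples.
* NetCDF/archive dialects of deposited observatory data are not parsed;
  users adapt them to the documented CSV schemas.
* Event categories (moderate/strong/severe/extreme) and multivariate
  community analyses are out of scope.
* With gap-joining enabled the identity between the net-anomaly series
  and threshold-baseline day-degrees holds only up to the in-envelope
  gap days (which contribute zero exceedance).
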