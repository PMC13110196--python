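# Methods

## Problem setting

Most clinical trial data are repeated measurements of the same subjects over
a protocol-defined visit schedule.  Systematic errors — protocol
misinterpretation, miscalibrated instruments, unit mix-ups, data fabrication
— tend to arise at the level of an investigational *site* and affect many of
that site's subjects at once.  `spotter` screens a long-format measurement
table for such site-level anomalies, and secondarily for individual subjects
with peculiar series, without any supervision or expectation model: every
site is compared against the rest of the study.

The pipeline is: clean → group equal-length series → summarise each
subject's series into scalar features → test each site's feature values
against all other sites → correct for multiplicity → flag.  A simulation
benchmark (anomaly injection with known truth) quantifies how reliably each
scoring method recovers planted anomalies.

## Cleaning

Records from unscheduled visits and all records of screen-failure subjects
are removed before analysis.  Unscheduled visits break the cross-subject
alignment of visit indices; screening failures contribute no analysable
series.  `clean_study` is idempotent.  Duplicate
(subject, parameter, visit) rows are rejected as a data error rather than
averaged — silent aggregation could mask exactly the anomalies being hunted.

## Time-series groups

Series are comparable only when they cover the same visits.  A *group* is a
parameter, a prefix `[1..L]` of the visit schedule, and every subject whose
missing-value fraction over those visits is at most `max_missing_ratio`
(default 0.30; a visit with no record counts as missing, and a subject with
no observed value in the window is never eligible).  Automatic discovery
walks L down from the longest observed visit index one step at a time,
accepting the first window with at least `min_group_size` subjects (default
25) and thereafter any shorter window whose eligible count grows by at least
`improvement_ratio` (default 20%, inclusive: a gain of exactly 20% is
accepted; count ties keep the longer window).  Only schedule prefixes are
searched — arbitrary sub-windows are not.  Subjects may belong to several
groups at once, and groups of length one are allowed because some
measurements are taken only once.

## Features

Each subject's series within a group is summarised into up to six scalars:

| feature | definition | anomaly it detects |
|---|---|---|
| average | mean of non-missing values | calibration shift |
| sd | sample SD (n−1) | implausible fluctuation |
| range | max − min | unit/magnitude errors |
| unique_value_ratio | distinct / non-missing count | duplication, rounding |
| autocorrelation | lag-1 Pearson over consecutive-visit pairs | artificial linearity |
| lof | local outlier factor among the group's series | extreme or fabricated patterns |

Design points worth stating explicitly:

* **Autocorrelation lag is fixed at 1.**  Lag-1 is the convention that
  detects the "add a constant to the previous measurement" pattern.  It
  needs at least two valid consecutive pairs and non-zero variance in both
  lagged subvectors; otherwise the value is undefined (NaN).
* **Unique-value equality is exact floating equality.**  Rounding in the data
  is precisely the signal sought, so no tolerance is applied.
* **Range of a length-1 series is undefined, not 0.**  A single value carries
  no dispersion information; emitting zeros would flood the site tests.
  Likewise sd, unique_value_ratio and autocorrelation are undefined for
  length-1 groups, leaving average and LOF.
* **LOF** uses the classical reachability-distance definition with Euclidean
  distances and neighbourhood `k = min(20, n_subjects − 1)`.  Missing
  entries are imputed with the per-visit median across the group (at most
  30% per subject by construction), preserving per-visit location structure
  without inventing within-subject trends.  Mean reachability is floored at
  1e−12 so exactly duplicated series do not divide by zero.  The
  implementation is written out rather than delegated so the duplicate floor
  and the tie-break (stable index order) are exactly as documented; an
  independent library implementation serves as a cross-check in the tests.

Undefined feature values propagate as NaN and simply drop out of the site
tests.

## Site scoring

Three methods convert a feature column into per-site verdicts.

**Kolmogorov–Smirnov.**  Each site's feature values are compared with the
pooled values of all other sites by the two-sided two-sample K-S test
(asymptotic p-value).  Sites of any size ≥ 1 are tested; a site with no
defined value for a feature is untestable for it and yields a missing row.

**Mixed model.**  An intercept-only linear mixed model with nested random
intercepts — site within country within region — is fitted per feature
column (REML, Powell optimisation; the single robust optimiser avoids both
the boundary collapse of quasi-Newton steps under moderate signal and the
cost of an optimizer retry cascade at true nulls).  Hierarchy levels with a
single entity are dropped from the model and reported with p = 1.  For each
entity, `lmm_draws` (default 1000) realisations of its random effect are
simulated from the conditional normal distribution N(BLUP, conditional SD),
widened by the fixed intercept's sampling SE.  The widening matters: entity
effects are deviations from the *fitted* grand intercept, and when a few
strongly anomalous sites drag that intercept, ignoring its uncertainty makes
every compliant site "deviate" significantly.  The median and SD of the
draws give the two-sided p-value p = 2·Φ(−|median|/sd).  Degenerate inputs
(constant column, < 2 sites, singular fit, zero draw SD) give p = 1 with a
logged warning.

**Average feature value.**  The baseline: each site's mean feature value,
with sites strictly outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the site means
flagged.  Boundary values are not outliers.  With fewer than 4 sites having
a defined mean the quartiles are meaningless and nothing is flagged.  The
method produces no p-value and ignores site size, which is why its false
positive rate is expected to exceed the other methods'.

**Multiplicity and flagging.**  All raw site-level p-values of one scoring
run — every site × feature × group for one parameter and method — form a
single family corrected with Benjamini–Yekutieli, which stays valid under
the arbitrary dependence created by re-using the same observations across
tests.  This widest-family choice is the most conservative defensible
reading.  The score is −log10 of the adjusted p (floored at 1e−300); a
site × feature is flagged when its **maximum** score across groups reaches
the threshold, default 1.3 (adjusted p ≈ 0.05).  Country- and region-level
mixed-model results are computed and reported (adjusted within their own
level's family) but never drive site flags.  The average method contributes
no p-values; its site × feature verdict is the OR of the per-group IQR
flags.

## Subject-level screening

Within one group, subjects are screened two ways: a 2-D similarity
embedding — classical metric MDS (principal coordinates) of the Euclidean
distances between imputed series, chosen over stress-minimising variants
for determinism and zero tuning, with axis signs fixed by the
largest-magnitude coordinate — together with a mean-distance-to-k-nearest
isolation statistic; and a two-sided extremity ranking of feature values,
|value − median| / MAD, descending.  Robust location/scale is used so a
single extreme subject cannot mask itself by inflating the spread estimate;
zero MAD (heavily rounded columns) falls back to absolute deviation from the
median.  The two views correlate: the subject with the highest LOF is almost
always among the most isolated points of the embedding.

## Anomaly injection

Six transformations plant a site-level anomaly of scalar intensity
("degree") at chosen target sites, each paired with the feature that should
detect it.  With m_s the pre-injection mean of all non-missing values of
the parameter at site s, d the degree, and s± an independent random sign:

* **average** — x′ = x + m_s·d.
* **sd** — x′ = x + s±·m_s·d per observation.
* **range** — one uniformly chosen non-missing visit per subject gets
  x′ = x + s±·|m_s|·d.  Scaling the outlier by the site mean keeps degrees
  comparable across parameters with different units.
* **unique_value_ratio** — d is a replacement ratio clamped to [0,1]; the
  first observation is kept and round-half-up(d·(n−1)) of the remaining
  non-missing values, chosen uniformly, are overwritten with it.
* **autocorrelation** — x′_t = x_t + d·x_{t−1} using *original* predecessors
  (no cascading, keeping the transform linear); first visits and values with
  a missing predecessor are unchanged.
* **lof** — d is an affected-subject ratio; each affected subject's series is
  redrawn from one of four non-normal shapes (uniform over the subject's
  range, exponential, near-constant with 1% jitter, two-point at min/max),
  then shifted and scaled to the subject's original mean and range.  The
  pool is configuration-extensible.

All injections leave non-target sites bit-identical, never alter the record
structure or missingness pattern, are the identity at degree 0, and are
bit-reproducible per seed.

## Validation protocol

One benchmark iteration: permute all subjects across the existing sites
(size-preserving, erasing any residual site signal), draw 3 target sites,
inject one scenario, rediscover groups, compute features, score with one
method, and flag on the feature paired with the anomaly type using the
max-over-groups rule.  Pooled over iterations, TPR = flagged anomalous /
all anomalous and FPR = flagged compliant / all compliant sites.
Cross-feature detections are logged but not counted.  Iteration seeds
derive deterministically from the base seed and the cell coordinates
(method, type, degree, iteration), so any single cell is reproducible in
isolation.

## Synthetic study generator

The generator emulates the *structure* of trial extracts while containing no
site-level signal by construction: value = subject baseline
(Normal(parameter mean, baseline SD)) + linear visit trend + residual noise,
with no site/country/region terms (an optional `site_effect_sd` knob exists
for mixed-model power experiments only).  Defaults, chosen once as a
realistic mid-size study: 1 region, 1 country, 20 sites × 15 subjects ×
8 visits; missing visits at 5% (baseline visit always kept); 30% of subjects
staggered to the first half of the schedule; 5% unscheduled-visit rate; 5%
screen-failure rate (such subjects hold only a screening visit).  The
staggered fraction must exceed ~0.25 for structural reasons: a shorter
window can gain at most f/(1−f) subjects, so smaller fractions sit on the
20% group-acceptance boundary and the generator invariant (staggering yields
a second group) would hold only for lucky seeds.  Four parameter presets
ship (alanine aminotransferase, creatinine, systolic blood pressure, and
weight rounded to integer kilograms, exercising the unique-value-ratio
path); all preset means and spreads are plausible synthetic values, not
estimates from any real trial.  The single-region/single-country default
matches the benchmark situation where regional and country signal has been
removed by permutation; the nested mixed-model path is exercised by
multi-country fixtures in the tests.

What the generator does *not* emulate — treatment-arm effects, correlated
parameters, non-linear pharmacodynamic trajectories, calendar-time drift,
real visit-window jitter — bounds what passing benchmarks show: they
demonstrate that the scoring machinery recovers planted site-level
distortions under clean null structure, not field performance on any
particular real study.

## Problem sizes and numerical choices

The shipped benchmark uses the default 20 × 15 × 8 study with the
mean-shift anomaly, all three methods, degrees {0.1, 0.25, 0.5, 1, 2} and
100 iterations per cell, and the null control uses 100 freshly generated,
permuted, no-injection studies — sizes chosen as the smallest at which the
pooled rates are stable to a few percent.  Other fixed numerical choices:
group-eligibility and IQR comparisons use exact arithmetic with a 1e−12
tolerance only on the ratio caps; K-S uses the asymptotic p-value for all
site sizes; adjusted p-values are floored at 1e−300 before the log; all
sub-seeds derive from CRC32 mixing and stay below 2^31.

## Known limitations

* Only numeric measurements are supported; categorical/ordinal/date data
  must be transformed upstream.
* Only schedule-prefix windows are discovered automatically; a protocol
  whose comparable series form a mid-schedule window needs manual groups.
* The mixed model assumes normal feature distributions; heavy-tailed
  features (LOF itself) can inflate its false positives relative to K-S.
* The average-value baseline ignores site size and flags small sites on
  chance extremes; it is included as a benchmark, not a recommendation.
* TPR/FPR from the synthetic benchmark apply to its experimental conditions
  only; thresholds for production monitoring should be reviewed against the
  cost of false positives in the specific trial.
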