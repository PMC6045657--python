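# Methods

This note documents the models, conventions, parameter defaults, and
numerical choices behind `axenic`, and what the synthetic-data tests do and
do not establish about real recordings.

## Sleep and activity scoring

A fly's record is a gap-free 1-minute grid of beam-crossing counts.  Missing
minutes (monitor error rows, grid gaps) are stored as NaN and treated as
*unobserved*, never as zero: a zero count is evidence of immobility, an
absent one is not.  Consequences of that choice:

* missing minutes terminate zero-runs in sleep scoring by default.  A
  permissive mode (`bridge_gaps_min`) bridges missing gaps up to a given
  length when flanked by zeros; bridged minutes then count toward episode
  duration, trading strict observability for episode contiguity;
* missing minutes are excluded from every rate denominator (activity per
  minute, sleep per 30-min bin).

Sleep episodes are **maximal** runs of ≥ 5 consecutive zero minutes.  A
sliding-window variant of the 5-minute rule would score the same minutes
asleep, so the distinction only affects episode bookkeeping, not totals.
Runs touching the record boundaries count if long enough — discarding real
sleep at the edges would bias totals downward.  Per fly, asleep + awake
minutes always sum to the observed minutes, and an episode spanning a bin or
day/night boundary contributes its minutes to each side, which preserves
that conservation under any binning.

Dead-fly removal drops any fly with ≥ 24 consecutive hours of zero counts
(boundary inclusive: exactly 1440 zero minutes is removed).  Zero beam
crossings is the only movement proxy the device has.  The filter is
idempotent and applied before any summary.

The day window is the half-open interval [lights-on, lights-on + 12 h), so
each cycle has exactly 720 day and 720 night minutes and the transition
minute is counted once.  Lights-on time is mandatory configuration for real
recordings — monitor files do not carry it, and silently assuming one would
misalign every phase statistic.

Folded daily profiles average all observed passes through each of the 48
half-hour cycle bins (bin 0 starts at lights-on).  Group profile bands
resample **flies**, the experimental unit — resampling minutes or bins would
understate between-animal variance.

## Arena metrics

Wall following is the arithmetic mean over frames of the centroid's distance
from the arena center, in mm; mean speed is the mean over consecutive frame
pairs of displacement over Δt.  Both are computed exactly as defined: no
smoothing and no jump filtering by default, because any filter changes the
estimand.  An optional maximum-displacement-per-frame filter is available
for tracking glitches.  Frames with missing positions drop out of both
numerator and denominator; a pair with a missing endpoint contributes no
speed term.

Arena center, radius, and mm-per-pixel calibration are required
configuration.  When chamber geometry was not logged, a minimum-enclosing-
circle estimator over all tracked points of an arena is provided as a
fallback; it bounds the radius from below (flies rarely touch the true wall
with their centroid), so configured geometry is preferred.  Sessions shorter
than 90% of the nominal 600 s are excluded, and longer records are trimmed
to 600 s so all flies contribute the same observation window.

## Courtship preference

Preference = time courting target A / total courtship time.  The denominator
is courtship time only — normalizing by the full hour would conflate
preference with vigor.  Trials under 60 s total courtship are omitted; the
boundary is inclusive (exactly 60 s stays), since the exclusion rule is
"less than one minute".  Target A is the conventional female, so values
above 0.5 mean the conventional female was preferred.  The group summary is
the sample median with a smoothed-bootstrap percentile interval; the sample
is sorted before resampling so results depend only on the multiset of
preferences, not input order.

## CHC abundance

Relative abundance = compound peak area / hexacosane internal-standard peak
area (arbitrary units), which makes the measure invariant to rescaling all
areas jointly.  Class totals sum relative abundances within linear alkanes,
branched alkanes, dienes, and monoenes; the class map must cover every
compound.  Group contrasts are mean differences with bootstrap CIs.  With
the typical three replicate sets per group the estimates carry a `low_n`
flag: the intervals are computed but should be read as rough.  Classical
two-way ANOVA on class × group is deliberately not reimplemented; the
estimation summary carries the same information in effect-size form.

## Estimation statistics

* **Hedges' g** uses the df-weighted pooled SD and the small-sample
  correction J = 1 − 3/(4(n₁+n₂−2) − 1).  Zero pooled SD is an error, not a
  zero: the standardized effect is undefined there.
* **BCa intervals** follow the standard construction.  z₀ = Φ⁻¹ of the
  proportion of bootstrap statistics below the estimate, counting ties at
  half weight; a proportion of exactly 0 or 1 is clamped to 1/(B+1) with a
  warning.  Acceleration a comes from the jackknife (leave-one-out within
  each of the two independent groups, n₁+n₂ pseudo-values).  Resampling is
  within-group.  A degenerate bootstrap distribution yields a zero-width
  flagged interval.  If the adjusted interval fails to contain the point
  estimate beyond numerical tolerance, the code raises rather than report an
  incoherent record.  With z₀ = a = 0 the construction reduces exactly to
  the percentile interval, and the implementation is cross-checked against
  SciPy's independent BCa implementation in the test suite.
* **Smoothed bootstrap medians** perturb each resample with N(0, h²) noise,
  h by Silverman's rule 0.9·min(SD, IQR/1.34)·n^(−1/5) (falling back to the
  SD when the IQR is zero).  h = 0 recovers the ordinary bootstrap; a
  constant sample gives a zero-width interval.
* **Effect bands** on |g|: trivial ≤ 0.2 < small ≤ 0.5 < moderate ≤ 0.8 <
  large.  A value exactly on a threshold goes to the lower band — the
  conventional open-interval band definitions leave boundaries unassigned,
  and the lower band is the conservative choice.
* **Pro-forma p**: Welch's t by default; a permutation alternative
  (exhaustive when feasible) is exposed because the convention behind
  published pro-forma values varies.  No pipeline decision ever consumes a
  p-value, and no multiplicity adjustment is applied anywhere.
* Default 10,000 resamples for reported intervals; tests use fewer where the
  quantity under test does not depend on resolution.  All resampling is
  reproducible from explicit seeds.

## Synthetic data: what it emulates

* **Monitors**: per fly, a two-state wake/sleep Markov chain at 1-minute
  resolution; Poisson counts at a phase-specific rate while awake, zeros
  while asleep.  This makes ground-truth sleep exact for testing the
  zero-run scorer.  Defaults (day rate 1.8, night rate 1.0 crossings per
  awake minute; entry/exit day 0.05/0.15, night 0.12/0.03) give daytime
  activity near one crossing/min, ~7.5 day-sleep and ~24 night-sleep minutes
  per 30 — the range typical of laboratory flies.  Dead flies emit zeros
  from a uniform onset in the first half of the record, guaranteeing the
  24-h criterion on records of ≥ 2 days.
* **Trajectories**: correlated random walk (heading persistence, Gaussian
  turning with SD 0.6 rad/frame at 10 Hz) plus an outward radial drift of
  `wall_bias`·speed, with specular reflection at the boundary.  With zero
  bias the stationary radial mean matches the uniform-disc expectation 2R/3;
  bias increases wall proximity monotonically over the operating range
  (≈ 0–1), saturating near the wall beyond that.  Defaults: R = 10 mm,
  600 s at 10 Hz, group speed 1.3 mm/s with 20% between-fly CV.
* **Courtship**: Poisson bout arrivals with gamma-distributed per-trial
  vigor (shape 1.5), exponential bout durations (mean 30 s, ~20 bouts/h),
  Bernoulli(preference) target choice, capped at the hour.  Inter-bout
  statistics are free generator parameters, not calibrated to any dataset;
  the vigor spread deliberately produces occasional sub-60-s trials to
  exercise the exclusion filter.  Default preference 0.7 — the magnitude the
  two-choice assay is designed to resolve.
* **CHC tables**: lognormal areas (CV 0.25) around a panel of eight typical
  female *Drosophila* cuticular hydrocarbons spanning the four classes, with
  optional additive per-class group shifts.
* **Pupation**: normal days-to-pupation sampler (controls mean 5.0 d,
  SD 0.9) with a 1.33-day germ-free delay by default, at group sizes
  213/112.

One global seed expands to per-fly substreams through counter-based spawn
keys, so identical seeds give bit-identical outputs and adding flies or
groups never perturbs earlier streams.

**What passing synthetic tests does not show:** real monitor data violate
the two-state Poisson model (bout-structured activity, circadian ramps,
anticipation peaks), real trajectories have tracking noise, centering
artifacts and wall-contact geometry the random walk lacks, and real
courtship bouts are autocorrelated.  The synthetic suite validates the
*scoring and inference machinery* — definitions, filters, interval
calibration, determinism — not the biological realism of any particular
parameter value.

## Problem sizes and calibration checks

The test suite exercises the pipeline at the study's native scale: groups of
56 flies (the design minimum for resolving moderate effects), 6-day monitor
records, 600-s sessions, and 92 courtship trials.  Calibration suites run
scaled bootstrap resolution (1,000 resamples) where only coverage, not
interval smoothness, is at stake: BCa coverage on normal data (n = 50/group,
500 replicates), effect-size recovery at n = 56 (1,000 replicates), a
100-replicate all-null full-study false-positive control, and a
200-replicate recovery check of an injected activity-rate difference
(2-day records, sleep disabled so the injected Poisson rate difference is
itself the estimand).

## Known limitations

* The monitor reader handles the 42-column and reduced tab-delimited
  dialects, not binary acquisition formats.
* No circadian rhythmicity analysis (periodograms, phase estimation) and no
  sleep-architecture contrasts beyond the episode tables.
* BCa intervals at n = 3/group (CHC) are reported but weakly justified;
  the `low_n` flag marks them.
* The trajectory generator's wall bias is monotone but saturating; it is a
  device for producing tunable thigmotaxis, not a mechanistic model of fly
  wall-following.
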