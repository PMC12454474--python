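# Methods

This note documents the models, parameter choices and numerical conventions
behind `loopscale`, and what the synthetic-data studies do and do not show.

## Generative kinematic model

Each stroke is generated with a half-sine vertical-velocity profile: for
amplitude `A` (cm) and peak velocity `v_p` (cm/s),

```
v(t) = ± v_p · sin(π t / d),   d = π A / (2 v_p),
y(t) = ± A · (1 − cos(π t / d)) / 2.
```

The half-sine is a standard minimum-jerk-like approximation of ballistic
pen strokes; its virtue here is the exact closed-form relation between
amplitude, peak velocity and duration, which gives the test suite analytic
oracles (sample counts, net displacement, durations). Any smooth unimodal
profile with an exact amplitude/peak/duration relation would serve equally.
Trials are rendered on a globally uniform time grid (positions evaluated
analytically per stroke), so sampling is exactly uniform and each stroke
occupies `round(rate · d)` samples up to one-sample discretization. A
smooth horizontal half-sine bulge plus constant drift makes loops
loop-like; the horizontal channel carries no analysis content.

**Planning model.** A subject's per-stroke peak velocity is planned from
the condition's *target* amplitude (1 cm, 4 cm, or the alternating
large/small targets of the mixed condition):

```
v_p = baseline_velocity + scaling_gain · (target − 1) + N(0, velocity_noise_sd),
```

while the *realized* stroke amplitude varies around the target,
`A ~ N(target, amplitude_sd · target)`, floored at 0.05 cm. Two
consequences are deliberate:

1. The condition coefficient of the VS regression estimates
   `3 · scaling_gain` for the LL design (the 1→4 cm step is 3 cm), and the
   size covariate's coefficient tends to zero — so the carried-forward
   condition slope is a direct, per-subject measure of the generative gain.
   Had velocity been driven by the realized amplitude instead, the size
   covariate would absorb the entire effect and the condition coefficient
   would estimate zero for every subject, making the carried-forward
   statistic uninformative by construction.
2. Within-condition amplitude variability is *required*: with
   `amplitude_sd = 0`, vertical size is an exact affine function of the
   condition dummy, the design matrix is rank-deficient, and the regression
   is refused with an explicit collinearity error. The dummy and the size
   covariate remain strongly collinear by design (that is the nature of the
   statistic); a condition-number warning is logged above 1e4.

**Defaults and units.** `baseline_velocity` mean 1.7 cm/s (SD 0.3 across
subjects), `scaling_gain` mean 1.67 (cm/s)/cm (SD 0.25), `amplitude_sd`
0.12 per cm of target, `velocity_noise_sd` 0.1 cm/s, sampling rate 100 Hz
(typical for pen tablets), 8 loops per trial, 3 trials per condition. The
baseline and gain means follow from near-isochrony of loop writing at
roughly 15 s per 8-loop trial (stroke duration ≈ 0.95 s in both the 1 cm
and 4 cm conditions). The noise SDs are calibrated once, analytically, so
that the generator sits in the high-reliability regime the task is known to
occupy — a two-item Cronbach's alpha of about 0.95 for small-loop peak
velocity (`α₂ = 2r/(1+r)` with `r = 0.09/(0.09+0.01)`); this calibration
also keeps slope-estimation noise small relative to between-subject gain
variance, which matters for the standardized-beta recovery study below.
The mixed condition orders loops large, large, small, small, … (cursive
"LLeeLLee", each letter one loop), i.e. 4 large + 4 small loops per trial.
Group effects on the kinematic parameters default to zero and are
configurable.

## Score model

Per group (HC / rMDD / cMDD = 85 / 97 / 49 by default), general depression
and well-being are bivariate normal with means and SDs 24.6 (7.2) /
32.1 (9.4) / 52.5 (11.4) and 24.2 (6.7) / 22.5 (6.7) / 16.6 (5.9)
respectively; anhedonia is well-being reverse-coded (× −1). The
`depression_anhedonia_corr` parameter (default 0.55) is the target *pooled*
correlation across the whole cohort; the generator solves analytically for
the within-group residual correlation that achieves it given the group
mean separation (pooled covariance = between-group + within-group part).
An infeasible implied residual correlation (|ρ| ≥ 1) raises a configuration
error.

Each subject's scaling gain is coupled to their population-standardized
anhedonia with standardized slope `anhedonia_vs_effect` (default −0.16):
`gain = gain_mean + gain_sd · (e·z_anh + sqrt(1−e²)·η)`. This makes the
population standardized regression coefficient of gain on anhedonia exactly
`e`, so the truth table supports exact and Monte-Carlo recovery tests. At
`|e| = 1` the subject noise vanishes and sample recovery is exact.

## Stroke extraction

Preprocessing: order-2 zero-phase Butterworth low-pass at 10 Hz on y
(configurable; conventional pen-tablet values), central-difference
velocity with one-sided endpoints. Trajectories must be strictly
increasing in time, uniform within 10%, and at least 1 s long; shorter
records than the filter's padding requirement are refused.

Segmentation: boundaries at sign changes of vertical velocity, a run of
exact zeros breaking at its midpoint. Candidate segments smaller than
`min_stroke_size` (default 0.1 cm, a jitter-suppression convention) merge
into the following segment (a trailing undersized remainder merges
backwards), and adjacent segments with the same excursion direction are
then coalesced — so a sub-threshold jitter reversal never changes the
stroke count. Strokes span half-open index ranges, tile the trial exactly,
and carry `duration = (end − start)` sample periods, matching the
closed-form `d = πA/(2 v_p)` within one sample on noise-free input.
Vertical size is net displacement (not peak-to-trough extent). Peak
vertical velocity is the maximum *absolute* velocity, so up and down
strokes pool into one analysis.

Validity: at least 10 segments per trial; any pen-up sample invalidates the
trial (the acquisition protocol this emulates re-runs such trials instead).
LLee labelling uses the exact (exhaustively searched) 1-D two-means split
on vertical size with the midpoint of the cluster centres as threshold;
centre ratios under 1.5 flag the trial ambiguous, and ambiguous trials are
excluded from LLee analyses. Participants with fewer than 10 valid labelled
segments in either LLee class are excluded from LLee analyses only.

## Statistics

The VS regression is plain OLS (solved by least squares; an explicit
missing-condition or collinearity error otherwise, minimum 4 segments).
Slopes are z-scored across participants per design for reporting;
dimensional models standardize internally, so raw and z-scored slopes give
identical betas. Group models report the overall F against the
intercept-only model computed from the residual-sum-of-squares reduction
(F is defined as 0 when the outcome carries no variance). Dimensional
models standardize outcome and predictors (n−1 SDs) before OLS, so
coefficients are standardized betas with two-sided t-based p-values
(statsmodels supplies the fit). p-values are uncorrected for multiple
testing, and each battery model drops incomplete participants listwise,
with counts logged.

The battery registry holds exactly 20 models: per design, the 3-level
group test on small-condition velocity, large-condition velocity and VS,
the lifetime (HC vs combined MDD) test on VS, anhedonia on all three
outcomes, general depression on VS, and the joint anhedonia + general
depression model on VS; general depression on the two LL velocity outcomes
completes the set. Further contrasts (e.g. lifetime-coded velocity tests)
are available through `fit_group_model` directly.

Cronbach's alpha uses the standard item-variance form with n−1 variances;
items are individual segments in acquisition order concatenated across
trials (3 × 16 = 48 items at most per class, 24 per LLee class). The
incremental curve filters participants to those with ≥ k segments at each
width (no imputation) and records the retained n; negative alphas are
reported unclipped. Slope stability refits the VS regression on each
participant's first k segments per condition, k = 2, 4, …, 48, reporting
across-participant mean, SD and mean absolute change between consecutive
widths; widths where a participant's regression is infeasible skip that
participant with a log entry.

## Reproducibility

One global seed fans out through `numpy.random.SeedSequence` into one
child stream for the subject draw and one per participant for kinematics,
so cohorts are bit-reproducible and participant k's data do not depend on
cohort size. The pipeline writes every intermediate table as plain
delimited text; every number in the summary is recomputable from those
tables.

## Monte-Carlo studies and problem sizes

The validation suite verifies (sizes chosen to give tight Monte-Carlo
error at interactive runtimes): statistic oracles on 50 random fixtures at
1e-10; beta recovery on 500 cohorts of n = 231 (mean estimated anhedonia→VS
beta within 2 MC SE of −0.16) and the null rejection rate on 1000 cohorts
(binomial band around 5%); Spearman–Brown agreement of the incremental
alpha under a parallel-items generator (4000 × 48 matrix, tolerance 0.02);
and slope-dispersion monotonicity over 50 replicated noisy cohorts. The
replicate-level studies draw per-stroke measurements directly from the
stroke measurement model rather than re-rendering and re-segmenting time
series; the time-series path is itself validated against the generating
parameters (3% attenuation bound, one-sample durations) so the shortcut is
exact up to that bound.

## Known limitations

* The generator omits pen pressure, tilt, mid-trial pen lifts, tremor and
  fatigue drift, and simulates scale totals, not item-level responses.
  Passing tests therefore demonstrate correctness of the estimators under
  the stated model, not robustness to real-tablet artifacts.
* Real acquisition software may define vertical size as peak-to-trough
  extent and use different (unpublished) filter settings; both are
  configurable but the defaults are conventions.
* The measured 4-segment alpha for the small "ee" strokes of the mixed
  condition runs below the separate-condition classes (size-class
  transitions make small-stroke peaks noisier after filtering) — a
  qualitative analogue of mixed-condition measures being less clean than
  separated ones.
* The LL1-vs-LL4 contrast spans different trials, so slow state changes
  between trials load onto the VS slope; the stability curve's bump when
  trial-2 segments enter illustrates exactly this sensitivity.
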