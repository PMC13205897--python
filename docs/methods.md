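# Methods

`pbrtqc` simulates and benchmarks patient-based real-time quality
control (PBRTQC) for serum tumor markers.  A laboratory analyzer is
monitored not with manufactured control material but with the stream of
patient results itself: a statistic of the stream is tracked against
control limits fitted on error-free data, and an excursion signals an
analytical error.  The package implements three monitoring schemes, a
calibrated synthetic stream generator, a bias-injection protocol and an
evaluation harness, and makes the comparison between the schemes
reproducible end to end.

## The three monitors

**Traditional EWMA.**  The monitored statistic is the exponentially
weighted moving average of the raw results,
`EWMA_t = (1 − λ)·EWMA_{t−1} + λ·x_t`, with the weight tied to a block
size N through `λ = 2/(N+1)`.  Control limits sit at the empirical
0.05% and 99.95% percentiles of the statistic on error-free training
data, targeting a false alarm rate (FAR) of 0.1%.  N is chosen by
exhaustive search over {5, 7, 10, 40, 70, 100, 130, 160, 190, 220}: a
candidate is admissible only if its FAR stays at or below the desired
rate (DFAR, 0.1%) on *both* the training and the validation partition,
and among admissible candidates the fastest mean detection wins (ties
to the smallest N).  If no candidate is admissible the limit half-width
is widened to 1.25× and the search repeats; a run that still fails is
returned with an explicit `uncontrolled` status.

**Pre-classified monitoring.**  Tumor-marker streams mix subpopulations
with very different baselines; monitoring each against its own limits
removes between-group variance.  The chain: (1) the two analytes most
co-ordered with the target are mined from per-barcode support; (2) each
sample with complete companions maps to a 3-vector via
value → multiple-of-median → ln → IQR normalization, per analyte, with
all statistics frozen from training; (3) OPTICS clusters the mapped
training cloud (reachability ordering, xi = 0.05, `min_samples`
= max(50, 1% of n)); noise points merge into the nearest cluster
centroid so every sample carries a label; (4) an RBF-kernel SVM learns
the cluster labels and is accepted only at ≥ 90% stratified held-out
accuracy (penalty escalated over C ∈ {1, 10, 100}, hard error
otherwise); (5) samples without companion results fall back to a
maximum-posterior assignment from per-group normal densities on a
global Box–Cox scale weighted by group priors; (6) within each group
the raw sub-series is filtered — sym4 wavelet soft-threshold denoising
(universal threshold, 3 levels), Box–Cox (maximum-likelihood λ),
z-score, then a centered trimmed moving mean — and the filtered value
is alarmed against per-group 0.05%/99.95% limits.  All filter
parameters are frozen at training time; refitting on monitored windows
would absorb the very bias being sought.

**Residual-network monitoring.**  A small feed-forward network
(inputs → 20 → 10 → 1, tanh hidden units, linear output) learns the
mapping from patient covariates — age, sex, patient category,
department, diagnosis, and a baseline feature — to the Box-Cox +
z-score transformed result.  Monitoring then runs the same EWMA
machinery on the *residuals* (transformed actual − predicted): the
predictable inter-patient variation is stripped out, the monitored
noise shrinks, and the same absolute bias becomes a larger relative
shift.  Training values are truncated to the [p1, p99] band before the
transform fit; truncation is never applied at monitoring time (biased
values must reach the monitor).  The training partition is split
70/15/15 at random into internal train/validation/test subsets; Adam
updates run epoch by epoch (batch 256, learning rate 1e-3) with early
stopping on the internal validation MSE (patience 20) and best-weights
restore.  Training is deterministic given the seed.

The *baseline* input is intended to be the patient's most recent prior
result on the same analyte.  Synthetic streams contain no repeat
visits (one barcode, one patient), so the encoder substitutes the
training-median constant; a `patient_id` column would activate the
prior-result path.  The feature is therefore inert in all shipped
experiments.

## Bias injection

Two step-change error types are simulated on test-partition windows:
constant error `x′ = x + n·TEa·median` and proportional error
`x′ = x·(1 + n·TEa)`, with TEa = 25% and n ∈ {−2, −1, 0, +1, +2}.  The
median is the training-set median — the marginals are far too skewed
for the mean.  Per condition, replicate windows of consecutive records
start at independent random positions; within each window the bias
onset is drawn uniformly with at least 500 samples (configurable) on
either side, so every replicate has a false-alarm-bearing prefix and a
measurable detection delay.  Biased values are clipped back into the
analyte's reportable range.  Every replicate carries a traceability
record (sampling start, error type and size, onset, affected barcodes,
seed) from which it can be replayed bit-exactly.

## Evaluation

FAR is the alarm fraction on error-free windows, averaged over
replicates.  NPed counts results from the bias onset up to and
including the first alarming sample (an alarm on the first biased
sample scores 1).  tANPed drops the single largest replicate NPed and
averages the rest; undetected replicates are censored at the post-bias
window length and the detection count is reported alongside, and a
condition with no detections at all reports a NOT_DETECTED sentinel
rather than a number.  Models are compared per condition with a
classical paired t-test on replicate NPeds sharing an injection record
(α = 0.05, uncorrected — a documented choice).  Replicate windows are
drawn once per error type and shared across multipliers, so severity
comparisons are paired and censoring lengths match across |n|.

Monitored windows are warm-started on the last 5000 training inputs
(the statistic is stationary when the window begins); only window
positions are scored or plotted.

## The synthetic generator

The generator emulates the statistical features PBRTQC reacts to, not
the biology producing them.

*Marginals.*  Values are drawn on the log scale and exponentiated.
The total log-scale SD per analyte comes from the published-summary
mean/median ratio via `σ = sqrt(2·ln(mean/median))` (a log-normal
identity), e.g. σ ≈ 1.51 for CEA.  A Pareto factor (shape 1.5)
multiplies a `tail_mixture_weight` = 2% subset, supplying the extreme
upper tail; the sample is then rescaled so its median equals the
preset's reference median *exactly*, clipped to the reportable range
and rounded to two decimals.  Heavy right skew is targeted
qualitatively (sample skewness ≫ 5 for CEA); matching fourth moments
of clipped mixtures is ill-posed and not attempted.

*Covariates.*  Age (discretized truncated normal, 18–90), sex, patient
category, department and diagnosis are sampled with fixed frequencies;
their effects enter additively on the log scale and are rescaled so
that the covariate block explains exactly `covariate_effect_fraction`
of the log-scale variance (default 0.5, exposed as a knob — the share
in real data is unknown).  An ordinary linear fit on the true design
recovers R² ≈ the requested fraction.

*Panels.*  For pre-classification experiments the generator emits the
target plus two companion analytes keyed by barcode.  Latent groups
(default 2) shift the log-values of all three analytes jointly by
`group_separation` (default 6) times the within-group log-SD; the
within-group SD defaults to 0.35 — pre-classified subpopulations are
far more homogeneous than the pooled stream — which makes TEa-scale
shifts resolvable within a group.  The heavy tail in panels is
*sample-level*: one Pareto factor elevates the target and its
companions jointly, as a pathological extreme co-elevates the markers
a clinician co-orders; such samples migrate toward (and are absorbed
by) the high group in mapped space, exactly the behavior
pre-classification exploits.  A configurable 10% of rows lack both
companions, exercising the fallback grouping.  A latent `group` column
is retained for testing only.

*Splitting.*  Streams are chronological; the first 80% splits 60/40
into train/validation and the final 20% is the test partition from
which replicate windows are drawn.

What passing tests on this generator do **not** show: robustness to
calendar-time drift (weekday/seasonal case-mix), assay imprecision
profiles, true inter-analyte biology, repeat-visit autocorrelation, or
free-text diagnoses.  The generator's subpopulations are cleanly
separated by construction; real pre-classification contends with
overlapping, drifting groups.

## Numerical and design choices

- **EWMA initialization** (unstated in the usual chart definitions):
  `EWMA_{−1}` = training-input mean; windows warm-start on the last
  5000 training inputs.
- **Quantiles**: linear interpolation between order statistics
  (type 7); alarms use strict inequalities; fitting the limits on
  fewer than 2000 statistic values emits an extrapolation warning.
- **Limit escalation**: the half-width about the limit midpoint is
  multiplied by 1.25, applied uniformly to any model whose train or
  validation FAR exceeds the DFAR; failure after escalation is an
  explicit `uncontrolled` status, never silent.
- **Wavelet stage**: sym4, 3 decomposition levels, soft universal
  threshold estimated from the finest detail band (MAD/0.6745) and
  frozen.  Soft thresholding overshoots near very large spikes
  (Gibbs), which a negative Box–Cox exponent would blow up into huge
  negative transforms; the denoised series is therefore clamped to the
  analyte's reportable range before Box–Cox.  Per-group limits are
  read off the statistic produced by the *run-time* filter path on the
  training series (training context prepended), so the training
  exceedance is ~0.1% by construction.
- **Mean filter**: centered trimmed moving mean, window 15, trimming
  the 2 smallest and largest values per window.  The width dilutes
  isolated physiological spikes that would otherwise inflate the upper
  limit and blind the monitor to positive biases; the trimming removes
  the impulse response entirely (one extreme or misrouted sample no
  longer drags its 14 neighbors toward an alarm) while a sustained
  shift passes at full height.  Both choices were calibrated during
  design against gross-error detectability and FAR control; windows of
  31 and above lose FAR control on validation data.
- **Fallback densities**: one global Box–Cox λ for the target (a
  common scale is required for posterior comparison), per-group normal
  (μ_g, σ_g) with cluster-frequency priors; exact posterior ties go to
  the lower group id.
- **OPTICS scaling**: reachability computation is quadratic, so
  clustering runs on a seeded random subsample capped at 8000 points;
  remaining points adopt the nearest cluster centroid before the
  classifier is trained.
- **Degenerate inputs**: constant series pass the filter chain as
  constants (Box–Cox λ pinned to 1, z-scale guard at σ = 0);
  non-positive values entering Box–Cox are shifted by 1 − min and the
  shift recorded; unseen covariate categories map to a reserved
  encoder level with a warning, never a crash.

## Problem sizes and known limitations

The test suite runs the comparison at desk scale — streams of
15–20k records, 2000-sample windows, 4–5 replicates per condition,
five seeds — chosen so the full suite completes in a couple of minutes
while the directional results (residual monitoring detects threshold
biases the raw-value monitor misses; gross biases are detected at
least as fast as threshold biases) are stable across seeds.  The
acceptance script runs the spec-scale sizes (50,000-record streams,
3000-sample windows).

Two limitations worth knowing:

- Per-group 0.05% control limits need long error-free series.  At
  ~3k samples per group the filtered statistic (autocorrelated over
  the filter window) supports only a few hundred effectively
  independent values and validation FAR occasionally escapes the
  escalated limits; at ~12k per group (the 50k acceptance scale) FAR
  is controlled across all probed seeds.  Small deployments should
  expect the same.
- The raw-value EWMA monitor is nearly blind to ±1 TEa biases on
  marginals this skewed (its empirical limits span the spike-driven
  tail), so its tANPed at threshold biases is usually the censored
  post-bias window length.  This is the regime the comparison is
  about, not an artifact.
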