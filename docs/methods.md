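# Methods

This note documents the analysis conventions, the generative model behind the
synthetic sessions, the numerical choices, and what the validation suite does
and does not establish.

## Trial and window conventions

Trials are 210 frames at 30 Hz: 1 s pre-stimulus and 6 s post-stimulus, with
stimulus onset at frame 30 (0-based).  All windows are half-open frame
intervals:

| window | frames | seconds rel. onset |
|---|---|---|
| baseline (F₀) | [0, 30) | [−1, 0) |
| evoked response | [45, 60) | [0.5, 1.0) |

The evoked window starts after the 0.5 s stimulus (and photostimulation
train) ends and closes before licking can begin, so it isolates the
sensory/photostimulation-evoked transient from response- and reward-related
activity.  Trials with licking inside the window are expected to be excluded
upstream of the evoked-response statistics.

## Preprocessing

The neuropil coefficient is the slope of a robust simple regression of the
somatic on the neuropil trace, clipped to [0, 1].  Robust = iteratively
reweighted least squares with Tukey bisquare weights (tuning 4.685), MAD
scale, at most 50 iterations, relative tolerance 1e-8.  The implementation is
vectorized across neurons so a whole session is one call; a unit test checks
the scalar path against `statsmodels.RLM` with the same ψ-function.  The
regression is fit on concatenated full-session traces (a per-trial option
exists but is noisier); when a session is very long the fit subsamples frames
evenly (cap 40,000 samples/neuron), which leaves the slope estimate
essentially unchanged.

ΔF/F uses the per-trial baseline mean F₀.  Trials with F₀ ≤ 1e-6 × the
session median fluorescence are excluded and logged rather than
offset-corrected, because adding an offset biases the ΔF/F ratio.

One consequence of per-trial ratio normalisation worth knowing: with ongoing
(spontaneous) transients, the expected evoked-window ΔF/F on a blank trial is
slightly positive — transients are positive-going and the baseline is a noisy
divisor.  Any statistic of the form A − (B + C) over condition means (the
linear-sum deficit below) inherits minus one copy of this offset.  At the
sparse activity levels of this preparation the offset is ≈0.002 ΔF/F and
negligible; it grows with spontaneous event rate × amplitude.

## ROC statistics

All selectivity/choice metrics are Mann-Whitney AUCs (pair counting with the
half-tie convention), which a test verifies against brute-force pair
enumeration.  Directional significance uses one-tailed Wilcoxon rank-sum
tests at α = 0.05 per direction, uncorrected across neurons: detected
fractions are meant to be compared against the nominal per-direction 5%
false-positive rate, which is how the type-I calibration is reported.
Time-resolved ROC uses one-frame bins with optional boxcar smoothing.

Inside the resampling null (10⁴ iterations by default) the activation test is
a vectorized normal-approximation rank-sum with tie-corrected variance and
continuity correction; it matches `scipy.stats.mannwhitneyu`'s asymptotic
p-values to machine precision in the rejection region, and the observed
statistic inside that procedure is computed with the same test so null and
observed are exchangeable.

## Photostimulation analysis

Target zones are inclusive 15 μm (the spiral diameter) around each spiral
site; a soma within both groups' radius is assigned to the nearer site, and
everything else is network.  The default activation comparison is control TS
vs. TS+PS trials (a catch-vs-PS switch exists).  The linear-sum deficit per
target neuron is mean(TS+PS) − (mean(TS) + mean(PS)); negative values mean
the photostimulation response is smaller in the presence of sensory drive
than additivity predicts.  Network sensory suppression is
mean(TS+PS) − mean(TS) per TS-responsive network neuron with the count of
activated targets within an inclusive 200 μm radius as the spatial covariate.

## Session-level inference

Each session contributes two photostimulation conditions.  Mean-centering
subtracts the within-session mean of each variable across the two condition
rows (idempotent; centered pairs sum to zero), isolating within-session
variation from session-level offsets.  The multiple regression z-scores every
predictor and the response, so coefficients are standardized and invariant to
affine rescaling of the raw inputs; collinear or constant designs raise an
error naming the offending columns.  The resampling null draws, per
iteration and session, two with-replacement subsamples of the control TS
trials sized to the two photostimulation conditions, recomputes the choice
deviation and the activated-target count on each fake condition, and records
the mean-centered correlation; the observed correlation's percentile uses the
mid-p convention.  The fake "TS+PS" subsample is compared against the full
control TS set, mirroring the real TS-vs-TS+PS activation test.

## The synthetic session generator

The generator produces the statistical structure the analyses consume, not
realistic movies.  Per neuron and trial a set of discrete events (amplitude
in ΔF/F units at stimulus onset, plus sparse spontaneous events) is passed
through a single-exponential calcium kernel (τ = 1 s, instantaneous rise —
a GCaMP6s-like decay suffices for window statistics); raw fluorescence is
F₀ · (1 + signal) plus a shared slowly-fluctuating neuropil trace scaled by
the true contamination coefficient plus white noise.

Key defaults (units; rationale):

* `n_neurons=250`, `fov_size_um=470`, 210 frames at 30 Hz — the imaging
  geometry of the experiment class.
* `frac_contra_coding=frac_ipsi_coding=0.14` — sparse coding ensembles;
  preferred-stimulus amplitudes Γ-distributed with means 0.18 / 0.12 ΔF/F
  (contra responses larger).
* `trial_mix` — TS+PS 15%, TS 15%, PS 15%, catch 15%, unilateral 40%; TS
  trials therefore run at twice the rate of each TS+PS condition, which the
  resampling null requires.
* `spont_rate_hz=0.05`, `spont_amp=0.1` — mostly silent neurons; this keeps
  the ratio-normalisation offset (above) negligible.
* `noise_sd=0.04` ΔF/F per frame; `neuropil_coeff_true=0.7`.
* Photostimulation: two 30-neuron target groups selected by a noisy
  selectivity score (top/bottom); per-group responder fraction drawn
  U(0.4, 0.95) — response mapping is an imperfect predictor of task-time
  responsiveness, so ~19 of 30 targets activate on average with large
  session-to-session spread; responders fire per trial with probability 0.9
  and amplitude ≈0.3 ΔF/F; non-responders have no functional opsin and never
  fire.  A configurable number of non-target neurons is placed inside target
  zones (imperfect spiral specificity).
* Sensory-photostimulation interaction: on TS+PS trials a target's
  photostimulation event is scaled by 1 − s·(1 − q) with s =
  `suppression_strength` (0.4) and q the neuron's TS drive clipped at
  `sparing_scale` (0.035 ΔF/F) — strongly whisker-responsive cells are
  spared, non-coding cells are fully suppressed.  On bilateral trials
  ipsi-coding sensory events are attenuated by 70% (contra-coding by 10%),
  reflecting contra-dominant competition; this is also why ipsi-coding
  targets fall below the sparing knee at the threshold stimulus.
* Network suppression: activated targets exert a distance-decaying
  (200 μm length scale) suppressive drive on non-zone neurons, stronger on
  followers tuned opposite the stimulated group's selectivity direction
  (cross-ensemble inhibition).  Suppression is expressed as a bounded
  negative ΔF/F event — a multiplicative gain on zero sensory drive would
  make suppression of non-coding followers invisible.  A sparse random set
  of followers is positively coupled instead.
* Choices: P(report contra) = logistic(4·(contra − ipsi) + β·n_activated)
  with β = `bias_coeff_true` (0.025 logit per activated target by default,
  giving a standardized within-session effect of ≈0.3); the lick side maps
  through the symmetric/asymmetric contingency and misses are drawn
  independently of the stimulus (0.10 on whisker trials, 0.90 on
  catch/PS-only trials, so photostimulation alone rarely evokes licking).

All sub-streams derive from one `SeedSequence`, so equal seeds give
byte-identical sessions.

## What the validation shows — and what it does not

The acceptance suite runs the complete pipeline on 20 synthetic sessions of
150 neurons × 400 trials (sizes chosen to keep the suite at desk scale while
preserving per-zone ensemble composition), plus lighter evoked-level
simulations for the resampling-null coverage.  Passing shows that the
implementation is internally consistent: calibrated null statistics, exact
oracle agreement for the AUC, recovery of the known neuropil coefficient,
responder counts, choice-bias coefficient and suppression phenomenology, and
~95% coverage of the resampling null under exchangeability.

It does not show that real data satisfy the generator's assumptions.  In
particular the generator has discrete tuning classes (real selectivity is a
continuum), instantaneous-rise kernels, stationary noise, no motion or
registration artifacts, no slow drift, and selection effects only through the
modelled score noise.  Two known small biases at measured-class resolution:
selectivity false positives inside target zones pull the contra-coding
deficit slightly negative, and the ΔF/F ratio offset adds ≈−0.002; both are
far below the suppression effects being detected and are covered by the
contrast-based tests.

## Numerical details and degenerate inputs

Empty label classes yield NaN (not errors) in ROC metrics; empty trial
subsets yield empty results.  Constant neuropil raises a degenerate-fit
error.  The psychometric threshold is undefined (flagged, NaN) when 0.5 lies
outside [floor, ceiling].  Ties in target selection break by neuron id;
dual-zone somata go to the nearer spiral.  The resampling percentile uses
mid-p; degenerate null iterations (no variance in fake counts) are dropped
and excluded from the percentile denominator.
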