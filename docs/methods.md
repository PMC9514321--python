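# Methods

## Overview

`gazedecode` implements an analysis pipeline that asks whether
trial-by-trial perceptual decisions (did the observer see a
near-threshold target?) and the confidence in those decisions can be
read out from two peripheral signals recorded at 500 Hz: the
microsaccade rate and the pupil size. The task structure is a yes/no
detection experiment under adaptation-induced blindness (AIB): each
trial presents a drifting-adaptor period (60 s on the first trial of a
block, 6 s afterwards), a 0.5 s inter-stimulus interval (ISI), and a
1 s target window, followed by a response screen. A session is 4 blocks
of 43 trials; per block the target falls on the two "positions of
interest" (top-left, bottom-right) in 65% of trials, on the six other
positions in 15%, and is absent (catch) in 20%. Nearest-integer
rounding of those proportions (28 + 6 + 9 = 43 per block) is the only
allocation that reproduces the session totals of 56 + 56 interest, 24
other and 36 catch trials, and is adopted as the schedule rule.

Because no recordings ship with the package, every stage is driven by a
synthetic-session generator with full ground truth, and the test suite
treats that ground truth as the oracle.

## Conventions

Time in ms at a fixed 2 ms sampling interval; gaze in degrees relative
to the central fixation bullseye with x rightward and y upward (the
handedness is a package convention — screen-coordinate handedness is
not otherwise constrained); pupil in arbitrary tracker units (a.u.);
0-based sample indices and half-open `[start, end)` intervals
everywhere. Missing samples are explicit boolean validity flags per eye,
never sentinel values, because sentinels corrupt filtering. Recordings
are a plain CSV dialect (`time_ms, lx, ly, rx, ry, lp, rp, lvalid,
rvalid`) rather than vendor binary formats; converting an EyeLink ASC
dump to this dialect is a line-by-line column selection.

## Synthetic sessions

The generator emulates the features of real binocular recordings this
pipeline is sensitive to:

* **Fixational drift** — a mean-reverting (Ornstein–Uhlenbeck) 2-D
  random walk shared by both eyes (diffusion 0.001 deg²/s per axis,
  relaxation 1/s, stationary SD ≈ 0.02 deg), plus independent per-eye
  white tracker noise (SD 0.005 deg).
* **Microsaccades** — event times from an inhomogeneous Poisson process
  with a 120 ms refractory gap; the rate in each trial period is
  `base + coupling · latent state` (base 1.2 events/s). Each event is a
  minimum-jerk displacement in a direction that steers back toward
  fixation once the accumulated offset exceeds 0.15 deg (producing the
  square-wave-like pattern of real fixational saccades). Amplitudes are
  log-uniform on 18–42 arcmin; peak velocity follows the main sequence,
  `v_peak = 60 (deg/s)/deg × amplitude`, with lognormal multiplicative
  scatter of σ = 0.12 by default. The 0.12 default reflects the tight
  within-observer amplitude–velocity relation seen in fixational eye
  movements (within-subject main-sequence correlations ≈ 0.9); it also
  keeps the two candidate clusters the detector assumes (noise vs
  saccades) actually separable, which is what the detection oracle
  tests rely on. The main-sequence quality-control check is instead
  exercised at 20% velocity scatter (see the acceptance script), where
  detected events still correlate at r ≈ 0.7–0.8.
* **Pupil** — a slow AR(1) baseline around 1000 a.u. (stationary SD
  8 a.u., lag-1 coefficient 0.998 at 2 ms), a Gaussian target-locked
  dilation bump (30 a.u., SD 200 ms) in every trial, and per-period
  offsets `coupling · latent state` applied with 100 ms cosine ramps so
  that coupling never masquerades as a partial blink.
* **Blinks** — full blinks (both pupils and gaze missing, ≈150 ms) at
  4/min and partial blinks (a sharp 35 a.u. dip, exceeding the
  20 a.u./sample criterion at its edges) at 1.5/min.
* **Behavior** — latent visibility is Bernoulli(0.5) per non-catch
  trial and 0 on catch trials; the reported decision flips the latent
  state with probability 0.1. Confidence has its own latent Bernoulli
  state, optionally coupled to features via a second 6-vector.

The coupling vector is the planted signal: entries 1–3 offset the
saccade rate (events/s) and entries 4–6 the pupil (a.u.) in the
adaptation/ISI/target periods when the target is (latently) visible.
Zero coupling produces exact label-feature independence, the null used
for calibration checks.

`sample_feature_table` is a documented feature-level shortcut that
draws per-trial features directly from the same generative model
(Poisson rates, Gaussian pupil in z-units) without rendering traces.
Decoder calibration studies that need hundreds of synthetic
participants use this path; the trace-rendering path is exercised by
the detection and preprocessing stages.

What the generator does **not** emulate: pupil foreshortening and
gaze-position artifacts, saccadic suppression of the pupil signal,
session-length drifts in tracker calibration, oblique-effect anisotropies
in microsaccade statistics, and any genuine physiological link between
adaptation state and eye behavior — couplings are planted, not modeled.
Passing tests therefore demonstrate that the pipeline recovers what it
assumes, on data satisfying its assumptions; they say nothing about
effect sizes in real observers.

## Preprocessing

Full blink events are maximal runs where both eyes' pupil is missing,
padded ±200 ms; partial blinks are runs where the combined pupil
changes by more than 20 a.u. per sample, padded the same way;
overlapping events merge (full wins). The combined pupil averages the
eyes when both are valid, takes the single valid eye otherwise, and
linearly interpolates across gaps and blink spans using the nearest
valid flanking samples (nearest-value fill at the edges, where the
recording is silent on what lies beyond). The per-sample derivative for
the partial-blink rule is computed on the combined signal *before*
interpolation. Sessions with more than 45% interpolated samples are
flagged `excluded` rather than silently dropped. The filter is a
zero-phase 4th-order Butterworth at 10 Hz (filter family and order are
a package choice — zero-phase avoids lag in period means; 4th order is
the standard pupillometry default). The z-transform pools the union of
all adaptation/ISI/target samples of the session (response screens
excluded); whether the original normalization pooled blocks or not is
unknowable from the text, and pooling per session is the simpler rule.

## Microsaccade detection

Per eye, horizontal and vertical velocities come from a 5-point
smoothed central difference at 500 Hz (the tracker's own instantaneous
velocity stream is not available for CSV input; the 5-point estimator
is the standard noise-robust choice); speed is `√(vx²+vy²)` averaged
over the eyes, and the acceleration trace is the same operator applied
to speed. The recording is tiled into consecutive 1 s windows from t=0
(sliding windows would over-count) and the six highest velocity peaks
per window become candidates; peaks inside blink pads are excluded.
Three features per candidate — peak velocity, initial and final
acceleration (signed extremum in the 12 ms before/after the peak; the
window length is a package choice) — are z-transformed across the
candidate set, reduced by PCA keeping components with eigenvalues above
5% of the largest, and clustered by 2-means (seeded, 10 restarts). The
cluster with the larger mean raw peak velocity is the saccade cluster;
exact ties break toward the smaller cluster, saccades being rarer than
noise peaks.

Each saccade-labelled candidate extends from its peak while the speed
stays above `max(3 deg/s, 20% of peak)` — the 3 deg/s floor matches the
mean-velocity filter's lower bound. Amplitude is the binocular-mean
gaze displacement between onset and offset (arcmin); mean velocity is
amplitude over duration. The physiological filters (duration ≥ 8 ms,
amplitude 10–120 arcmin, mean velocity 3–120 deg/s) are conjunctive;
overlapping survivors merge keeping the higher peak. A session passes
main-sequence QC iff the Pearson correlation between amplitude and
peak velocity exceeds 0.6. The saccade rate is events per second per
period, an event belonging to the period containing its velocity peak.

## Features

Per trial: saccade rate and mean z-scored pupil over each of the three
periods (6 features); total blink time overlapping the trial; and a
flag for trials where the binocular-mean gaze (gaps linearly
interpolated first, then all samples checked) strays more than 0.8 deg
from the screen centre during the three periods. Fixation is taken as
(0, 0) since the bullseye is central; the binocular mean is used for
the distance because neither eye is privileged.

## Decoding

L1-regularized logistic regression (liblinear) on the 6 features.
Metrics come from 10×10-fold stratified cross-validation: accuracy at
the 0.5 probability threshold and AUC per test fold, 100 folds.
Standardization is fit on the training folds only and applied to the
test fold (a `standardize` switch allows global scaling; within-fold is
the leak-free default). The inverse penalty C is grid-searched over 31
log-spaced values in [1, 10³] to maximize mean AUC, with ties going to
the smaller C (sparser model). By default the same folds serve
selection and reporting, which mirrors the original analysis and
carries a small optimistic bias; `nested=True` runs an inner 5-fold
selection per outer fold instead. Reported weights always come from a
fit on all standardized trials at the chosen C.

Variants: *both* pools the two positions of interest (class imbalance
left as-is by default); *per* fits one decoder per position and
averages metrics; *best* keeps the position with the higher AUC;
*balanced* undersamples the majority class to the minority size, 20
seeded repeats averaged (the repeat count is a package choice). The
confidence decoder reuses the machinery with sure/maybe labels on
all / yes-only / no-only trials; a participant whose minority
confidence class has fewer than 2 trials is excluded with a flag, and
the fold count is capped at the minority class size (10-fold CV is
impossible below 10 minority trials; the original text does not say how
such cases were split). The group decoder is leave-one-participant-out:
C is chosen by CV on the pooled training participants, standardization
is fit on them, and one accuracy/AUC pair is recorded per held-out
participant.

## Statistics

The permutation test reassigns each participant's "yes" labels
uniformly at random (class counts preserved exactly, asserted per
draw), reruns the decoding, and averages the metric across
participants; `p = (1 + #{null ≥ observed}) / (1 + n_perm)` (add-one
estimator, never 0). The default reruns the C grid search per
permutation — the conservative reading — with a `reuse_c` switch that
re-uses each participant's observed C; the permutation count defaults
to 1,000 and is configurable for desk-scale runs.

The Bayesian paired t-test is the JZS Bayes factor: a Cauchy prior
(scale 0.707, the default of the software family the statistic comes
from; exposed as a parameter) on the standardized effect size,
integrated by quadrature over the inverse-gamma mixture scale. Evidence
bands for BF10 are (1, 3] anecdotal, (3, 10] moderate, > 10 strong; at
or below 1 the data favor the null. The test suite cross-checks this
integral against an independent implementation that marginalizes the
noncentral-t density over the Cauchy prior directly.

Weight summaries report per-feature mean weights with one-sample Bayes
factors, the across-participant correlation between saccade-rate and
pupil weights per period, and the mean per-participant correlation
between decision- and confidence-decoder weight vectors; zero-variance
degeneracies are reported as QC flags. The blink control compares
per-participant mean total blink duration between yes and no trials
with a paired t-test and the paired Bayes factor.

## Problem sizes and numerical choices

The analysis drivers and the acceptance script use desk-scale sizes
chosen as the package's own defaults: 3 rendered participants in the
analysis scripts; one full 172-trial rendered session for the
main-sequence check; 10 feature-level participants × 100 permutations
(C grid-searched once per participant and reused across permutations —
the null mean of the AUC does not depend on C) for the null-AUC check;
200 outer replicates at 19 permutations for the type-I calibration
(with 19 permutations, `p ≤ 0.05` is exactly the event that the
observed statistic beats every permutation, level 1/20); 50 seeded
participants for weight-sign recovery; 500 staircase runs for threshold
recovery. Degenerate inputs raise typed errors (`FormatError`,
`ConfigurationError`, `DegenerateSignalError`,
`UnrecoverableSignalError`) rather than propagating NaNs; candidate
sets that cannot be clustered (fewer than two, or identical features)
yield an empty event list with a QC flag.

## Known limitations

* The generator's couplings are linear and additive; real
  visibility–oculomotor relations need not be.
* The headline decoding accuracies of the original study depend on its
  seven human observers and are not reproducible from synthetic data;
  the package instead verifies the machinery (calibration under the
  null, recovery of planted signal, the individual-vs-group
  dissociation) at desk scale.
* The detector's 2-means step assumes two well-separated clusters in
  the candidate features; recordings whose noise peaks overlap the
  saccade velocity range (e.g. very noisy trackers) will lose the
  smallest saccades to the noise cluster.
* Saccade direction is deliberately not a feature, and periods are
  summarized by single means; finer temporal binning is out of scope.
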