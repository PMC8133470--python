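# Methods

`gazexpert` implements a complete analysis chain for 250 Hz gaze recordings
made while observers view omnidirectional footage on a 3840×1920
equirectangular frame: synthetic trace generation, event segmentation,
physiological quality control, trial-level feature aggregation, and
participant-wise resampled classification of expertise (novice /
intermediate / expert). This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic
experiments can show.

## Geometry

Gaze positions are pixels on the equirectangular frame. Displacements map to
visual angle at 360° per frame width horizontally **and 360° per frame
height vertically** — the convention under which a 2400 px horizontal step
is a 225° sweep and a 1000 px vertical step is 187.5°. The vertical rule is
not the physically standard equirectangular mapping (which would be 180° per
frame height); it is kept because it is the convention the rest of the
pipeline's constants were defined against, and it is configurable. Seam
wrap-around (folding horizontal displacements across the ±180° boundary) is
available via `wrap_x=True` but off by default for the same reason.

## Event detection

Per-sample angular speed is a two-point forward difference at the native
4 ms step, with no smoothing (an optional pre-filter can be added upstream;
the detector itself consumes raw speeds). Pairs touching a device-flagged
invalid sample are NaN, not numbers.

* **Saccades**: maximal runs of speed > 40°/s. Runs separated by a single
  finite sub-threshold sample are merged (single-sample flicker), and runs
  separated by short all-invalid stretches (< 25 samples, i.e. below blink
  scale) are bridged, so a saccade interrupted by a tracking dropout remains
  one saccade. Runs spanning fewer than 3 inter-sample steps (12 ms) are
  discarded. Short invalid runs directly flanking a detected saccade are
  attached to it: during a dropout abutting a saccade the true onset/offset
  is unknowable, and the cleaning rules exist to remove exactly such
  saccades.
* **Gaps**: runs of ≥ 25 consecutive flagged-invalid samples (≥ 100 ms)
  become blink/tracking-loss gaps. Shorter invalid runs stay embedded in
  whatever event surrounds them.
* **Fixations**: complement intervals between saccades and gaps; intervals
  shorter than 50 ms are rejected. Dispersion is the I-DT bounding-box sum
  (max x − min x) + (max y − min y) over valid samples.
* **Smooth pursuits**: fixation-like intervals with dispersion > 100 px.
  No dedicated pursuit detector is attempted; the operational definition is
  "a wide, slow fixation", which is what a velocity-threshold detector can
  support.

Events are defined on inter-sample (pair) intervals, so fixations, pursuits,
saccades, gaps and rejected short intervals tile each trial's timeline
exactly — a property the test suite asserts.

## Cleaning

Trials with a tracking ratio (valid samples / total) below 0.75 are dropped,
with a per-participant ledger. Individual saccades are removed when the
first sample is invalid, when any sample is invalid, or when kinematics
exceed physiological bounds: peak velocity > 1000°/s, |peak acceleration| or
|peak deceleration| > 100,000°/s². "Invalid" here means flagged by the
device **or** sitting at the (0;0) error encoding: a raw export that leaves
(0;0) samples unflagged produces the impossible 10⁴-°/s-scale speeds that
the velocity/acceleration bounds are designed to catch. Saccade amplitude is
the path-length definition — mean sample-to-sample angular speed × event
duration — which for a straight saccade reduces to the chord but counts the
full travel of a curved one. Invalid samples are never interpolated;
affected saccades are removed whole. A saccade violating several rules is
removed, and counted, once.

## Features

Each trial becomes 46 named values: fixation and saccade frequency (events
per second of trial duration) plus average/SD/min/max of eleven measures
(fixation duration and dispersion; saccade duration, amplitude, mean and
peak acceleration, peak deceleration, mean and peak velocity; pursuit
duration and dispersion). The SD uses the n−1 denominator and is defined as
0 for a single event. Trials missing an event type are dropped by default
(configurable to keep-with-NaN). Frequencies are literal counts per second;
the historical population tables this package is calibrated against print
"frequency" values that numerically equal mean duration / 1000, which is
dimensionally inconsistent, so those printed values are not used as rate
targets anywhere.

## Synthetic data

Trials are alternating hold events (fixations, and smooth pursuits with
probability `pursuit_fraction` = 0.25) separated by ballistic saccades.
Event statistics are drawn from log-normal distributions moment-matched to
per-class population targets and truncated to the printed ranges; where the
pipeline itself imposes an extra truncation (fixation dispersion is capped
below the 100 px pursuit split), the log-normal location is re-solved
analytically so the *truncated* mean still equals the target.

* **Saccades** follow a Beta(3.5, 3.5) speed profile (peak/mean ≈ 2.03,
  matching the tables' peak-to-mean velocity proportions). Amplitude and
  duration are sampled with rank correlation 0.85 through a Gaussian copula
  — a main-sequence-style dependence without which long-duration small
  saccades would be undetectable at the 40°/s threshold. The sampled
  amplitude/duration describe the *detected* (supra-threshold) event; a
  fixed-point solve stretches the full profile so its supra-threshold
  portion matches them, and deep sub-threshold tails (below 0.55×threshold)
  are not rendered. Durations are floored so peak velocity stays below the
  1000°/s cleaning bound and accelerations below 10⁵ °/s².
* **Holds** are straight drifts (direction mostly horizontal, steered toward
  the frame interior) plus smoothed micro-jitter, rescaled so the bounding
  box dispersion equals the sampled target exactly. Drift speed is capped at
  0.82× the saccade threshold; a fixation whose sampled dispersion would
  require faster drift has its duration lengthened instead. Pursuit drift
  runs at ≈ 26°/s, so pursuit duration is emergent (dispersion ÷ speed)
  rather than sampled: the tabled pursuit duration (~0.3 s) and dispersion
  (400–620 px) pairs are mutually inconsistent under any 40°/s
  velocity-threshold segmentation (620 px in 0.3 s is ≈ 190°/s), and
  dispersion is the far stronger class discriminator, so dispersion wins.
* **Calibration**: small closed-loop offsets (`simulate.CALIBRATION`)
  compensate systematic detector effects — threshold-crossing bins average
  below the threshold (+10% margin in the tail solve, +2 ms duration pad)
  and fixations inherit saccade tails (−16 ms duration pad). They were
  estimated once by comparing detected against nominal event statistics on
  large simulated samples and are fixed. With them, detected per-class means
  of fixation duration/dispersion, saccade duration/amplitude and pursuit
  dispersion land within ~±4% of their targets; peak velocity, mean
  velocity, the acceleration summaries and pursuit duration are emergent
  from the kinematic model (ordering across classes is preserved, absolute
  levels deviate 10–40%) and are treated as reference values, not calibrated
  targets.
* **Idiosyncrasy**: each participant draws i.i.d. zero-mean *relative*
  offsets (SD = `idiosyncrasy_spread`, default 0.05, clipped at ±0.6) that
  scale every measure of their class profile, so the expectation over
  participants equals the class value.
* **Device errors**: dropout bursts (geometric length, mean 3 samples) set
  samples to (0;0)/invalid at a default 0.6% sample rate; short
  valid-flagged position-spike bursts (default 2.5×10⁻⁴ bursts/sample)
  emulate tracking glitches and are what exercises the velocity- and
  acceleration-bound cleaning rules; 3.4% of trials are degraded below the
  75% tracking ratio. Defaults reproduce the order of magnitude of the
  recorded-data ledger (≈3% of trials lost, ≈5–8% of saccades removed).

What the generator does **not** emulate: head movement, stimulus-driven gaze
(no ball or player positions), vergence/depth, device-specific noise
spectra, pupil-size artefacts, or asymmetric saccade speed profiles (the
Beta profile is symmetric, so |peak deceleration| ≈ peak acceleration,
whereas real saccades decelerate more gently). Passing tests therefore show
that the *pipeline* recovers the statistical structure it assumes, not that
real recordings would classify at any particular accuracy.

## Classification protocol

One run draws a participant-wise split: 8 train + 2 eval participants per
class, every trial of a participant on exactly one side (asserted in code).
On the training side a k = 50-fold ensemble of linear SVMs (C = 1, one-vs-one
decomposition as implemented by libsvm, per-model standardization fit on its
own training rows) is built; model i trains on the out-of-fold data of fold
i. The ensemble predicts by averaging the models' per-class decision scores
and taking the arg-max (majority vote available). The experiment repeats
over n_runs independent splits with per-run seeds spawned deterministically
from the master seed. k is clamped to the smallest class count so
stratification keeps every class in every fold; k = 1 reduces to a single
direct fit.

Feature regimes: ALL uses all 46 features; SF re-screens features on each
run's training side with two-sided Mann-Whitney-U tests between every class
pair, keeping a feature when its minimum pairwise p-value is below
α = 0.011 (Kruskal-Wallis omnibus available); MFF takes the 7 features most
frequently in the per-run top-7 importance rankings (mean |weight| across
fold models; ties by total rank then name) from pilot ALL runs. The
half-relabel control relabels half of the expert participants as
intermediates each iteration and runs a binary participant-wise
classification: chance-level accuracy indicates a homogeneous expert class.

A sample-wise splitter (random rows, participants straddling both sides) is
included only to demonstrate identity leakage: with idiosyncrasy spread 0.5
it inflates mean leave-out accuracy by ≈ 25 points over participant-wise
splitting on otherwise identical data.

## Evaluation statistics

Accuracy is trace/total of the eval confusion matrix; per-class miss rate is
exactly 1 − recall. Run distributions are summarised by median and quartiles
(linear interpolation between order statistics) with Tukey adjacents — the
most extreme observations within 1.5×IQR of the quartiles. Chance level is
1/number-of-classes.

## Problem sizes used in the test suite

The stochastic end-to-end tests scale the free dimensions (the sources state
no trial duration) as the package's own choices: the class-recovery
experiment uses the full 12/10/13 participants × 52 trials at 8 s per trial,
spread 0.05, 100 runs with k = 50 (median accuracy ≈ 0.8, asserted ≥ 0.55);
the null experiment uses two zero-separation datasets (shared profile,
spread 0) of 52 trials × 6 s with 50 runs each at k = 10, asserting the
pooled mean within ±3 points of 33.33%; the leakage demonstration uses 16
trials × 6 s at spread 0.5 with 30 + 30 runs at k = 20; the relabel control
uses 12 expert participants × 16 trials × 6 s with the 100-iteration
protocol at k = 10. Event-level calibration checks use 160 error-free 20 s
trials per class (≈10⁴ events). The ensemble fold count only affects
variance, not the chance/recovery properties these tests assert.

## Known limitations

* The pixel→degree y-convention and the absence of seam wrap-around follow
  the recording pipeline's arithmetic, not spherical geometry; both are
  configurable.
* Saccade mean velocity and acceleration summaries are emergent and sit
  10–40% from the reference tables (class ordering preserved); conclusions
  that hinge on absolute kinematic levels should not be drawn from the
  synthetic data.
* The half-relabel control detects a *bimodal* expert class only when the
  relabelled half aligns with the sub-populations; with random halves the
  expected accuracy is chance regardless of structure.
* Real recordings exported by other vendors need a column mapping onto the
  documented sample dialect; validity semantics beyond the (0;0) convention
  are the caller's responsibility.
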