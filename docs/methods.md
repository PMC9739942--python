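# Methods

This note documents the models, the processing conventions, the synthetic
data the package is validated on, and the design choices made where the
underlying method descriptions in the literature leave room.

## Signal model and stride segmentation

The pipeline consumes linear (gravity-removed) tri-axial acceleration. All
estimators operate on the per-sample magnitude `‖a‖ = √(ax² + ay² + az²)`,
which is invariant under any rotation of the sensor axes; this is the
operational meaning of "unaffected by smartphone orientation" and is
verified end-to-end by applying random 3-D rotations to raw traces.

Step detection is deliberately simple: local maxima of the magnitude after
a trailing 10-sample moving average, subject to a minimum inter-peak
distance (default 0.3 s) and minimum prominence (default 0.5 m/s²). A
stride spans two steps of the same limb, so strides are the half-open
intervals from peak *i* to peak *i + 2* with *i* even — consecutive,
non-overlapping, one per two steps. Source descriptions of such pipelines
rarely specify the detector; every threshold here is configuration-exposed
and the detector should be treated as a stand-in when running on real
recordings.

Two conventions matter for reproducibility:

* **Features are computed on the unsmoothed magnitude.** Smoothing exists
  only to stabilize peak picking; computing `a_r` on a smoothed signal
  would bias it low.
* **`a_v` is the population (divide-by-n) variance** of the magnitude
  within the stride. A stride window is the entire population of its
  samples; fixing the convention keeps fitted `shin_park` constants
  comparable across implementations.

Candidate strides with duration outside [0.4 s, 4 s] are discarded: tested
walking speeds (3.3–5.9 km/h) imply durations near 1 s, and anything
outside that band is a segmentation artifact.

The moving average is trailing with a shrinking window at the start (sample
*i* averages the most recent ≤ 10 samples), so output length equals input
length and constants are fixed points. Whether such filters are centered or
trailing is usually unstated in method descriptions; trailing was chosen
because it is causal, and the choice is documented rather than load-bearing
(a constant lag shifts all windows equally and cancels in durations and
displacements).

## Marker kinematics and reference stride lengths

Marker trajectories are differentiated with finite differences — central
quotients at interior samples, one-sided at the endpoints (exact for linear
motion everywhere, for quadratics in the interior) — and each derivative
is smoothed with the 10-point moving average, derivative first, filter
second. Velocity repeats the pair on position, acceleration on velocity.

Reference stride lengths come from the heel marker. Stance phases are
detected where the filtered heel speed stays below 0.2 m/s for at least
0.1 s; the stride length is the ground-plane (x–y) displacement between
consecutive stance-phase centroids. On a treadmill the stance points barely
move in the room frame, so a configured belt speed adds
`belt_speed × inter-centroid interval`. The stance rule and the belt
compensation are this package's realization — stance thresholds and the
belt speed are parameters, not facts — and the ground plane/vertical
convention (x–y ground, z up) applies to all imported and synthetic
trajectories.

## The estimators and their calibration

Six models map stride features to a length (table in the README). Three
readings fix ambiguities in how the comparison models are commonly printed:

* The exponent in `d = K·a_r^0.1` is read as the **tenth root** (power
  0.1), consistent with the quarter-root in the Weinberg lineage; a power
  of 10 would be physically absurd.
* The Bylemans formula's typography is ambiguous; the canonical grouping
  `0.1·a_mean·(K/F)·a_r^(1/2.7)` parallels the Mikov fraction-plus-root
  form. An alternate grouping `0.1·a_mean·K·(F·a_r)^(−1/2.7)` is selectable
  (`variant="joint_root"`). Since `K` is fitted, the variants differ only
  in functional shape.
* Models written in the literature with *step* frequency and *vertical*
  acceleration are fitted here on *stride* frequency and *magnitude*
  features: the factor of two is absorbed by the fitted constants, and
  magnitude features keep the comparison meaningful when sensor
  orientation is arbitrary. A designated vertical axis can be substituted
  where one exists.

Calibration minimizes `Σ(d_est − d_ref)²` with closed forms: the projection
`K = Σ(d·x)/Σ(x²)` for single-constant models (x the model's per-stride
basis value), ordinary least squares on `(F, a_r^0.1)` without intercept
for the adaptive model (its equation has no intercept), OLS on
`(F, a_v, 1)` for `shin_park`, and a log-space OLS for `sharp_yu`. Within a
subject the height is constant, so `K1` and `h^K2` are not separately
identifiable; `K2` is fixed to 1 and `K1` absorbs the rest, leaving
predictions unchanged. An optional Levenberg–Marquardt polish of the
`sharp_yu` fit in the original space exists but is off by default (the
log-space solution is deterministic and sufficient). Rank-deficient designs
are rejected naming the collinear regressors. Fit-versus-grid-search
oracle tests confirm the closed forms reach the optimum.

The calibration protocol mirrors a two-stage evaluation design: per-trial
fits on the first 300 s of each (subject, position, speed) trial — 120
parameter sets for a 10 × 4 × 3 roster — and joined fits across speeds per
(subject, position) for free walking — 40 sets.

## The adaptive scheme

Stride frequency and magnitude range both track walking speed, so per-speed
profiles store the fitted `(K1, K2)` plus the tuning window's mean `F` and
mean `a_r`. At estimation time strides are processed in windows of
N (default 10, roughly ten seconds of walking — N is a design choice, not
an established value); the window's mean features are z-scored by the
spread of the profile centroids (so neither feature dominates by units) and
the nearest profile by Euclidean distance supplies the constants. Ties
break toward the lower-frequency profile, making selection independent of
profile ordering. Selection is causal within the window: window *w*'s
choice applies to window *w* itself.

With a single profile the scheme reduces exactly to the static model, and
its output is by construction the concatenation of per-window static calls.

## Evaluation metrics

Treadmill-style evaluation is per stride: signed errors
`e_i = d_est,i − d_ref,i` in cm. Free-walking evaluation is per trial:
`e = (d_est − d)/d × 100 %`. Summaries report MAE = mean |e|,
**SD = the sample (n−1) standard deviation of the absolute errors**, and
CV = SD/MAE, plus over/underestimation shares and the same triple within
each subset. The SD-of-|e| convention is fixed empirically: it reproduces
every printed CV in the published evaluation tables this package mirrors at
two decimals (the full twenty-triple sweep is a unit test), which a
signed-error SD need not. Zero error counts as underestimation so the two
shares always total 100 %. With fewer than two errors, SD and CV are
reported as undefined, never as 0. Display rounding is half-up to 2 dp.

## The CCA derivation stage

For each analyzed marker, `X1` holds the per-stride constants
`K = d_ref / a_r^0.1` and `X2` holds 20 candidates: stride frequency,
stride duration, and {mean, median, range} × {acceleration, velocity} ×
{x, y, z} from the marker's filtered kinematics ("vectors" in the source
description read as the velocity vectors defined alongside acceleration —
the only self-consistent reading). Columns are centered and scaled to unit
variance; zero-variance columns are dropped with a warning and exactly
collinear blocks are rejected naming the dependent columns (rank-revealing
QR).

CCA itself is the classical whitening + SVD construction:
`C11^{-1/2} C12 C22^{-1/2} = U S Vᵀ`, correlations = singular values
(clipped to [0, 1], non-increasing), weights back-transformed through the
whiteners. With a single-column `X1` the first canonical correlation equals
the multiple correlation √R² of regressing `K` on `X2`, which the tests
verify against an independent regression oracle to 1e-8. Ranking uses the
**standardized** first-pair weights (raw canonical coefficients are
scale-dependent), descending by absolute value with ties broken by column
order; a ranking whose first correlation is below 0.1 is flagged as noise.

## Synthetic gait: what it emulates, and what it does not

Within stride *i* of duration `T_i` the noiseless magnitude is

    m(τ) = b + A_i·sin(4πτ/T_i) + 0.3·A_i·sin(2πτ/T_i)

— a step harmonic at `2F_i`, a smaller stride harmonic at `F_i`
(left/right asymmetry), over a baseline `b` that defaults to
`1.35·A + 1 m/s²` so the magnitude stays positive. Gaussian i.i.d. noise
(default SD 0.2 m/s²) is added, and the three axes are the magnitude times
a fixed seeded random unit direction, making the magnitude exactly
rotation-controlled. Stride-to-stride variability is multiplicative jitter
on frequency (3 %) and amplitude (5 %).

Speed labels map to stride frequencies 0.80 / 0.92 / 1.05 Hz and to
amplitude factors 0.8 / 1.0 / 1.25 on the per-position amplitudes
(hand 4.0 > thigh 3.0 > upper arm 2.5 > pelvis 2.0 m/s²): faster walking
both quickens and hardens the signal, which is the premise the adaptive
selector relies on. These mappings are invented, monotone by construction,
and are configuration values — the study speeds are stated in km/h, not
frequencies.

True stride lengths follow either the feature-linear law
`d_i = K1*·F_i + K2*·a_r,i^0.1 + ε_i` (defaults `K1* = 0.80`,
`K2* = 0.25`, `ε` Gaussian with SD 2 cm) or an inverted-pendulum relation
on leg length (vertical excursion from the step-harmonic amplitude at
angular frequency `4πF`). Marker generation gives the heel flat stance
phases (35 % duty) with cosine-smooth swing advances along a straight
line, the 21.64 m rectangular loop, or a treadmill (stationary stance
points; the belt carries the distance); the remaining seven landmarks ride
the body path with phase-offset harmonics. One `numpy` Generator seeded
per scenario drives every draw, so identical scenarios are bitwise
identical.

What passing on this data does **not** show: the generator has no
soft-tissue or sensor-mount artifacts, no heavier-tailed or correlated
noise, no turning dynamics (the loop's heading changes only through the
heel path), no double-support subtleties, and its feature-to-length truth
is exactly the model family being fitted (by design, for parameter
recovery). Results on real recordings depend additionally on the step
detector matching the device's signal character.

## Problem sizes and numerical choices

Tests and the acceptance script scale problems to run comfortably on one
CPU: trials of 20–500 strides at 50–100 Hz, 100 derivation replicates of
200 strides, 100 random rotations, 20 oracle instances. Key numerical
choices: least squares via `numpy.linalg.lstsq` on explicitly checked
full-rank designs; CCA eigenvalue floor at 1e-14 of the largest (rank
issues are caught earlier by the QR check at 1e-8); stride pairing uses
peak parity, so one missed peak shifts at most the affected stride;
segmentation requires at least three peaks, else an empty result with a
warning rather than an error. Degenerate inputs (zero-duration windows,
non-positive measured distances, empty profile lists) are rejected with
specific messages.

## Known limitations

* The step detector is a generic peak picker; device- or gait-specific
  detectors will disagree on stride boundaries, and fitted constants are
  only comparable within one detector configuration.
* The decision window N and the nearest-centroid rule of the adaptive
  selector are design choices; the scheme's published description fixes
  neither.
* Sharp–Yu's height exponent is unidentifiable within a subject; fits
  report `K2 = 1` with `K1` absorbing the height term.
* Treadmill belt compensation assumes a constant, known belt speed.
* The free-walking loop's measured distance uses the loop geometry; chord
  shortening at corners makes stance-to-stance displacements slightly
  shorter than arc length, a property of the geometry rather than an error.
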