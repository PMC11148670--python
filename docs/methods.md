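# Methods

This note documents the models, conventions and parameter choices behind
`elbowcal`, in the order the pipeline uses them.

## Kinematic model and conventions

Quaternions are Hamilton, scalar-first, and passive: a stream attached to a
sensor or segment holds the rotation `global ← local`, whose matrix has the
local axes as columns in global coordinates. `q` and `−q` are the same
rotation and all comparison helpers treat them so. Public APIs take and return
degrees; radians are internal.

The global frame is X forward and Z up; gravity is −Z and a resting
accelerometer reads the +9.81 m/s² reaction along the case-frame image of +Z.
Anatomical segment frames are X anterior, Y cranial (longitudinal), Z lateral
(to the subject's right), so in a perfect upright N-pose every segment frame
is the same rotation of the global frame (forward, up, right).

The elbow angle triple is the **intrinsic Z–X′–Y″ factorization** of the
humerus-to-forearm relative rotation `R = Rᵤₐᵀ · Rₗₐ`:

* α about Z — flexion (+) / extension (−), range (−180°, 180°];
* γ about the floating X — carrying angle, range [−90°, 90°];
* β about Y — pronation (+) / supination (−), range (−180°, 180°].

With `R = Rz(α)·Rx(γ)·Ry(β)` the closed forms are `γ = asin(R₃₂)`,
`α = atan2(−R₁₂, R₂₂)`, `β = atan2(−R₃₁, R₃₃)`. Samples whose carrying angle
comes within 0.5° of ±90° are *flagged* (gimbal proximity) rather than
rejected — the split between α and β is ill-conditioned there, but elbow data
essentially never visits that band. Flexion and pronation are phase-unwrapped
along time with a 180° threshold; the carrying angle needs no unwrap by
construction. Sign conventions were fixed so that simulator flexion and
pronation are positive, and they match scipy's intrinsic `"ZXY"` convention
(cross-checked in the tests).

Frames are built from an axis pair by `frame_from_axes(primary, secondary,
roles)`: the primary axis occupies its column exactly, the third column is a
normalized cross product, and the secondary is recomputed by a second cross
product, so only its component orthogonal to the primary matters and the
result is right-handed with det = +1 for every role assignment. Axis pairs
within 1° of parallel raise a degenerate-frame error reporting the angle.

## Calibration methods

All three methods output, per arm segment, a calibration quaternion
`q0 = sensor ← segment`; runtime angles come from
`q_global←segment = q_global←sensor ⊗ q0`.

**N-Pose.** The middle 50% of the static window is used (the edges often
contain settling motion). Stillness is enforced as an orientation spread
< 2° about the chordal-mean quaternion; the accelerometer's mean direction is
compared against the vertical and a tilt above 10° is recorded as a warning
diagnostic. The thorax anatomical frame takes the gravity vector as its
cranial axis and the thorax sensor's forward direction (the case's −y under
the prescribed mounting), orthogonalized against the vertical, as anterior.
Both arm segments inherit this thorax frame at the calibration instant, so
`q0 = (mean sensor orientation)⁻¹ ⊗ q_thorax-frame`. The construction is
exactly invariant to a common heading rotation of all sensors. Two
consequences follow directly: an imperfect posture enters `q0` one-for-one,
and the subject's resting carrying angle is invisible to the method (it shows
up later as a carrying-angle offset).

**Functional.** The hinge axis of an oscillatory single-plane movement is the
first right-singular vector of the raw (uncentered) `(n, 3)` gyroscope
matrix. Centering is unnecessary because hinge oscillation reverses sign
across cycles; uncentered SVD also keeps the estimator well-defined for
single-lobe movements. The off-axis energy fraction
`1 − s₁²/Σsᵢ²` is reported as `residual_ratio` and the fit is rejected above
0.5 (movement not single-plane). The sign is disambiguated by the *first
movement lobe*: the projection of the gyro stream onto the axis is smoothed
(0.1 s moving average) and the sign flipped so the first significant lobe
(first sample exceeding 30% of the peak) is positive. Under the calibration
protocols the movement starts with flexion (resp. pronation), which makes the
returned axis anatomical +Z (resp. +Y). Recordings shorter than 2 s or with
peak angular speed below 0.3 rad/s are rejected as insufficient motion; both
thresholds sit far below the prescribed movements and far above sensor noise.

The upper-arm frame takes the flexion axis — estimated from the *lower-arm*
gyroscope (the olecranon is supported, so the forearm carries the hinge
rotation) and translated into the upper-arm sensor frame through the
window-mean orientations — as lateral (Z), and the window-mean upper-arm
accelerometer direction (gravity, i.e. cranial while the upper arm hangs
vertically) as the secondary cranial (Y) axis. The lower-arm frame takes the
pronation axis as longitudinal (Y); the movement is performed with the elbow
flexed 90°, where the global vertical points along the forearm's anterior
axis, so the vertical — mapped per sample into the sensor frame and averaged
— serves as the secondary *anterior* (X) axis. These role assignments are
pinned down by the closed-loop requirement that a perfectly instrumented
subject yields exact angles; the per-sample averaging of the vertical is
exact for symmetric pronation sweeps and robust to drift otherwise.

**Manual alignment.** Constant by construction: under the prescribed mounting
the segment axes are (X, Y, Z) = (−y, x, z) of the sensor case, a fixed
permutation whose quaternion is (√2/2, 0, 0, −√2/2). Its accuracy is purely
the accuracy of physical sensor placement.

## Accuracy metrics

Within each movement repetition, with reference angles θ_ref and test angles
θ_imu:

* ROM error = (max − min)(θ_ref) − (max − min)(θ_imu) — shift-invariant;
* RMSE = rms[(θ_ref − mean θ_ref) − (θ_imu − mean θ_imu)] — each series is
  demeaned by its *own* within-repetition mean, so RMSE is a pure
  waveform-shape error and exactly invariant to constant offsets;
* offset = mean(θ_ref) − mean(θ_imu) — the bias the demeaning removed.

Repetitions are cut at the minima of the dominant-axis angle after a 0.25 s
moving-average smoothing, with the trial boundaries acting as outer cuts;
minima need a prominence of 10% of the signal range and a spacing of at least
half the nominal period, and edge slivers shorter than a quarter of the
median window are dropped. A dominant-axis range below 10° is a flat-signal
error. When fewer full cycles than expected exist, the windows found are
returned with a warning rather than failing the trial. None of this touches
the metric definitions; it only decides the windows.

Aggregation follows the within-subject factor layout: repetitions are
averaged into each (subject, calibration, axis, task) cell, cells average
into per-calibration grand means. No filtering is applied to angle series
before metrics (configurable upstream if desired).

Time alignment of a real optical reference onto IMU timestamps (linear
resampling plus cross-correlation lag on the flexion axis) is only relevant
to the real-data adapter; simulated reference and test series share
timestamps by construction.

## Study statistics

The design is fully within-subject and balanced (every subject × calibration
× axis × task cell present; empty cells are an explicit error). Sums of
squares decompose exactly by marginal means; each within effect is tested
against its own subject×effect stratum. **Generalized eta squared** pools the
subject variance and *all* error strata into the denominator,

    η²G(effect) = SS_effect / (SS_effect + SS_subjects + Σ SS_error-strata),

the appropriate pooling for fully repeated-measures designs; it is computed
in-house because the pooling choice is the definition, and the tests verify
it against its closed form and against the routine's own SS decomposition.
Uncorrected F, df and p agree with statsmodels' `AnovaRM` (independent
cross-check in the tests). Sphericity is assessed per effect with Mauchly's
test on the effect's contrast-projected covariance (Kronecker products of
orthonormal Helmert-type contrasts; factors outside the effect averaged out,
which leaves both the Greenhouse–Geisser epsilon and Mauchly's W unchanged by
scaling); when Mauchly rejects at α = 0.05 — or the covariance is singular —
the Greenhouse–Geisser epsilon `tr(S)²/(k·tr S²)`, clamped to [1/k, 1],
rescales both degrees of freedom. Effect SS below 10⁻¹² deg² (micro-degree
excursions, i.e. numerical residue of an exact pipeline) are reported as
F = 0, η²G = 0 rather than as ratios of rounding noise.

## The virtual-subject simulator

The simulator provides what a lab would record — calibration trials and five
tasks with both ground truth (the optical stand-in) and corrupted IMU
streams — so the whole pipeline is testable at desk scale.

**Trajectories.** Single-plane movements are raised-cosine cycles starting at
the movement minimum, so a trial with *n* repetitions has exactly *n* maxima
and the first lobe moves in the positive direction (which the functional
sign rule relies on, mirroring the prescribed protocols). Flexion task:
10–130°; pronation task: ±80° at 90° flexion; flexion calibration movement:
15–50°; pronation calibration: ±80° at 90° flexion; the drinking,
box-off-shelf and circles tasks mix a dominant flexion cycle with
phase-locked pronation and trunk sway. All waveforms are C¹.

**Carrying angle.** γ(flexion) starts at the subject's baseline at full
extension and decreases by the subject's span (≤ 15°) at 130° flexion,
linearly or as a half-sinusoid. This is the one "corruption" that lives in
the ground truth itself: it makes the flexion calibration movement slightly
non-hinge (the functional axis picks up a tilt of roughly the ratio of
carrying rate to flexion rate) and it is invisible to the N-pose method.

**IMU corruption.** Sensor orientation = segment truth ⊗ nominal mounting ⊗
misalignment, then premultiplied by a heading random walk about the vertical
(Brownian, increment sd = rate·√dt, so the heading sd reaches the configured
rate, in degrees, after one second). The gyroscope is the central
finite-difference body rate of the corrupted orientation plus white noise —
for a fixed-axis rotation the finite difference is axis-exact at any step, so
the noiseless closed loop stays exact. The accelerometer maps gravity into
the corrupted case frame plus white noise; linear acceleration is omitted by
default. The imperfect N-pose applies small per-segment rotations during the
static trial only, and the trial's recorded truth is recomputed from the
perturbed orientations, so the internal-consistency invariant
(`truth_angles == elbow_angles(truth_orientations)`) holds for every trial.

**Default study conditions** (all overridable per config):

| parameter | default | rationale |
| --- | --- | --- |
| sampling rate | 60 Hz | typical wearable-IMU streaming rate |
| trial duration / repetitions | 15 s, 5 reps | matches the five-repetition protocol |
| cohort | 13 subjects | matches the study design |
| carrying baseline | U(8, 16)° | typical adult carrying angle |
| carrying span | U(5, 15)° | up to the reported 15° flexion-dependence |
| mounting misalignment | U(5, 10)°, random axis/sensor | realistic manual placement error |
| N-pose posture error | U(3, 10)°, random axis/segment | imperfect "arms straight" compliance |
| gyro noise sd | 0.02 rad/s | consumer-MEMS scale |
| accel noise sd | 0.2 m/s² | consumer-MEMS scale |
| heading walk | 0.05 deg/√s | slow magnetometer-free heading drift |

The zero-corruption configuration additionally zeroes the carrying baseline:
with both arm frames inherited from the trunk, a resting carrying angle is an
apparent N-pose error by construction, and the closed loop is meant to verify
numerics, not physiology.

**What the simulator does not model** — and hence what passing tests do not
show about real data: soft-tissue artefact beyond a heading walk (no
flexion-correlated skin motion by default), linear-acceleration contamination
of the accelerometer, magnetometer disturbance, optical-system errors
(landmark digitisation, marker cluster motion), and between-session placement
variability. Absolute error magnitudes on real recordings are therefore
expected to be larger than the synthetic ones; the *ordering* mechanisms
(posture error hits N-pose only, placement error hits manual alignment only,
axis misalignment produces flexion-correlated carrying crosstalk) are the
transferable content.

## Problem sizes

The shipped study runs use 13 subjects × 8 trials × 15 s × 60 Hz (900 samples
per trial) — the full factor structure of the design at a size where the
complete pipeline, including the ANOVA, runs in seconds. Monte-Carlo checks
(hinge-axis recovery, formula oracles, Euler round trips) use 1000 draws.

## Known limitations

* The repetition segmenter assumes cyclic movements with a clearly dominant
  axis; free-living activity would need a different segmentation.
* Mauchly's chi-square approximation is asymptotic; with very small cohorts
  (n − 1 ≤ contrast df) the covariance is singular and the implementation
  conservatively applies the Greenhouse–Geisser correction.
* The real-data adapter currently reads only the package's native trial
  schema; mapping an external deposit's layout requires a translator in
  `elbowcal.adapters`.
* Gimbal-proximal samples are flagged, not repaired; trials that genuinely
  dwell at ±90° carrying angle (not anatomically plausible) would need a
  different parameterization.
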