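"""Virtual subjects: ground-truth upper-limb kinematics and corrupted IMU streams.

The simulator emulates the recordings of an elbow calibration study: a static
N-pose, two functional calibration movements (elbow flexion 15-50 deg and
full-range pronation with the elbow flexed 90 deg), and five movement tasks
(pure flexion, pure pronation, drinking, box-off-shelf, circles), five
repetitions each. Ground truth is the segment orientation chain

    trunk -> upper arm -> forearm = upper arm (x) Rz(flexion) Rx(carrying) Ry(pronation)

with a flexion-dependent carrying angle (linear or half-sinusoid, up to 15 deg
of excursion over the 0-130 deg flexion range). Virtual IMU streams corrupt
the truth with per-sensor mounting misalignment, a heading random walk,
white gyroscope/accelerometer noise, and (for the N-pose trial) an imperfect
static posture — the error sources that separate the three calibration
methods on real data.

The global frame is X forward, Z up (gravity is -Z, so a resting
accelerometer reads +9.81 m/s^2 along the global +Z mapped into its case
frame); in a perfect N-pose every segment frame is X forward, Y up (cranial),
Z right (lateral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import MANUAL_ALIGNMENT_MATRIX
from .kinematics import elbow_angles
from .rotations import (
    matrix_to_quat,
    quat_from_axis_angle,
    quat_identity,
    quat_inverse,
    quat_multiply,
    quat_rotate_vector,
)
from .series import InertialRecording, JointAngleSeries, OrientationSeries

__all__ = [
    "SubjectProfile",
    "SyntheticTrial",
    "TASKS",
    "CALIBRATION_TRIALS",
    "ALL_TRIALS",
    "DOMINANT_AXIS",
    "SEGMENTS",
    "NPOSE_SEGMENT_QUAT",
    "NOMINAL_MOUNT",
    "GRAVITY",
    "carrying_angle_of_flexion",
    "generate_task_trajectory",
    "forward_kinematics",
    "corrupt_to_imu",
    "generate_subject_trials",
    "generate_study",
    "sample_profile",
    "DEFAULT_PROFILE_RANGES",
    "ZERO_CORRUPTION_RANGES",
]

SEGMENTS = ("thorax", "upper_arm", "lower_arm")
TASKS = ("flexion", "pronation", "drinking", "box_off_shelf", "circles")
CALIBRATION_TRIALS = ("npose_static", "fe_calibration", "ps_calibration")
ALL_TRIALS = TASKS + CALIBRATION_TRIALS

#: Reference-angle axis used to cut each task into repetitions.
DOMINANT_AXIS = {
    "flexion": "flexion",
    "pronation": "pronation",
    "drinking": "flexion",
    "box_off_shelf": "flexion",
    "circles": "flexion",
}

GRAVITY = np.array([0.0, 0.0, 9.81])  # m/s^2, reaction reading of a resting accelerometer

#: global <- segment orientation of every segment in a perfect N-pose:
#: segment X = global forward, Y = global up (cranial), Z = global right (lateral).
NPOSE_SEGMENT_QUAT = matrix_to_quat(
    np.column_stack(
        [np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), np.array([0.0, -1.0, 0.0])]
    )
)

#: segment <- sensor rotation when a sensor is mounted exactly as prescribed
#: (the inverse of the manual-alignment permutation).
NOMINAL_MOUNT = quat_inverse(matrix_to_quat(MANUAL_ALIGNMENT_MATRIX))

MAX_CARRYING_SPAN_DEG = 15.0
FLEXION_AT_FULL_SPAN_DEG = 130.0


def _identity_per(keys) -> dict[str, np.ndarray]:
    return {k: quat_identity() for k in keys}


@dataclass
class SubjectProfile:
    """Anatomy, sensor placement and noise parameters of one virtual subject.

    ``carrying_baseline_deg`` is the carrying angle at full extension;
    ``carrying_span_deg`` (at most 15) is how much it decreases by 130 deg of
    flexion, following a linear or half-sinusoid profile. Mounting
    misalignment and N-pose posture error are small per-sensor / per-segment
    rotations; noise terms are white (gyro rad/s, accel m/s^2) and the heading
    drift is a Brownian walk about the global vertical whose standard
    deviation reaches ``heading_drift_rate`` degrees after one second.
    """

    carrying_baseline_deg: float = 12.0
    carrying_span_deg: float = 10.0
    carrying_shape: str = "sinusoidal"  # or "linear"
    mounting_misalignment: dict = field(default_factory=lambda: _identity_per(SEGMENTS))
    npose_posture_error: dict = field(default_factory=lambda: _identity_per(SEGMENTS))
    gyro_noise_sd: float = 0.0
    accel_noise_sd: float = 0.0
    heading_drift_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrying_span_deg <= MAX_CARRYING_SPAN_DEG:
            raise ValueError(f"carrying span must lie in [0, {MAX_CARRYING_SPAN_DEG}] deg")
        if self.carrying_shape not in {"linear", "sinusoidal"}:
            raise ValueError("carrying_shape must be 'linear' or 'sinusoidal'")
        if min(self.gyro_noise_sd, self.accel_noise_sd, self.heading_drift_rate) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class SyntheticTrial:
    task: str
    truth_angles: JointAngleSeries
    truth_orientations: dict[str, OrientationSeries]
    imu_streams: dict[str, InertialRecording]
    profile: SubjectProfile


def carrying_angle_of_flexion(
    flexion_deg, profile: SubjectProfile, shape: str | None = None
) -> np.ndarray:
    """Carrying angle (deg) as a function of elbow flexion.

    Baseline at 0 deg flexion, decreasing by the profile's span at 130 deg,
    with a linear or half-sinusoid shape (the latter passes baseline - span/2
    at 65 deg).
    """
    shape = shape or profile.carrying_shape
    f = np.clip(np.asarray(flexion_deg, dtype=float), 0.0, None) / FLEXION_AT_FULL_SPAN_DEG
    f = np.clip(f, 0.0, 1.0)
    if shape == "linear":
        drop = f
    elif shape == "sinusoidal":
        drop = 0.5 * (1.0 - np.cos(np.pi * f))
    else:
        raise ValueError(f"unknown carrying-angle shape {shape!r}")
    return profile.carrying_baseline_deg - profile.carrying_span_deg * drop


_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([1.0, 0.0, 0.0])


def generate_task_trajectory(
    task: str,
    duration_s: float = 15.0,
    reps: int = 5,
    rate_hz: float = 60.0,
    profile: SubjectProfile | None = None,
) -> tuple[JointAngleSeries, OrientationSeries]:
    """Smooth (C1) ground-truth joint angles and trunk orientation for one trial.

    Single-plane tasks use raised-cosine cycles starting at the movement's
    minimum, so a trial with ``reps`` repetitions has exactly ``reps`` maxima
    of the dominant angle; multi-joint tasks add a phase-locked secondary axis
    and trunk motion. The carrying angle follows
    :func:`carrying_angle_of_flexion` throughout.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    profile = profile or SubjectProfile()
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    phi = 2.0 * np.pi * reps * t / duration_s
    raised = 0.5 * (1.0 - np.cos(phi))  # 0 -> 1 -> 0 per cycle, min-start

    trunk_rot = np.zeros(n)
    trunk_axis = _Z
    if task == "flexion":
        flexion = 10.0 + 120.0 * raised
        pronation = np.zeros(n)
    elif task == "pronation":
        flexion = np.full(n, 90.0)
        pronation = -80.0 * np.cos(phi)
    elif task == "drinking":
        flexion = 20.0 + 100.0 * raised
        pronation = 30.0 * np.sin(phi)
        trunk_rot = 5.0 * raised
        trunk_axis = _Y  # slight forward lean while reaching
    elif task == "box_off_shelf":
        flexion = 30.0 + 70.0 * raised
        pronation = 20.0 * np.sin(phi)
        trunk_rot = 8.0 * np.sin(phi)
    elif task == "circles":
        flexion = 40.0 + 40.0 * raised
        pronation = 40.0 * np.sin(phi)
        trunk_rot = 5.0 * np.sin(phi)
    elif task == "npose_static":
        flexion = np.zeros(n)
        pronation = np.zeros(n)
    elif task == "fe_calibration":
        flexion = 32.5 - 17.5 * np.cos(phi)  # 15 -> 50 deg oscillation
        pronation = np.zeros(n)
    elif task == "ps_calibration":
        flexion = np.full(n, 90.0)
        pronation = -80.0 * np.cos(phi)
    else:
        raise ValueError(f"unknown task {task!r}")

    carrying = carrying_angle_of_flexion(flexion, profile)
    angles = JointAngleSeries(t, flexion, carrying, pronation)
    # global-frame trunk sway applied on top of the upright N-pose orientation
    q_sway = quat_from_axis_angle(trunk_axis, trunk_rot)
    trunk = OrientationSeries(
        t, quat_multiply(q_sway, np.broadcast_to(NPOSE_SEGMENT_QUAT, (n, 4)))
    )
    return angles, trunk


def _elbow_quat(angles: JointAngleSeries) -> np.ndarray:
    qz = quat_from_axis_angle(_Z, angles.flexion_deg)
    qx = quat_from_axis_angle(_X, angles.carrying_deg)
    qy = quat_from_axis_angle(_Y, angles.pronation_deg)
    return quat_multiply(quat_multiply(qz, qx), qy)


def forward_kinematics(
    angles: JointAngleSeries,
    trunk: OrientationSeries,
    profile: SubjectProfile | None = None,
    posture_error: bool = False,
) -> dict[str, OrientationSeries]:
    """Segment orientation streams from joint angles and trunk orientation.

    The upper arm rigidly follows the trunk (the shoulder is held in its
    N-pose attitude; only the elbow articulates) and the forearm is the upper
    arm composed with the ZXY elbow rotation, so running
    :func:`elbowcal.kinematics.elbow_angles` on the output reproduces the
    input angles. With ``posture_error`` the profile's per-segment small
    rotations are applied (used for the imperfect static N-pose).
    """
    if len(angles) != len(trunk) or not np.allclose(angles.t, trunk.t):
        raise ValueError("angles and trunk series must share timestamps")
    profile = profile or SubjectProfile()
    q_ua = trunk.q.copy()
    q_la = quat_multiply(q_ua, _elbow_quat(angles))
    out = {
        "thorax": trunk.q.copy(),
        "upper_arm": q_ua,
        "lower_arm": q_la,
    }
    if posture_error:
        for seg in SEGMENTS:
            err = profile.npose_posture_error.get(seg, quat_identity())
            out[seg] = quat_multiply(out[seg], err)
    return {seg: OrientationSeries(angles.t, q) for seg, q in out.items()}


def _body_rates(q: np.ndarray, dt: float) -> np.ndarray:
    """Finite-difference angular velocity (rad/s) in the case frame."""
    n = q.shape[0]
    omega = np.zeros((n, 3))

    def rate(qa, qb, step):
        dq = quat_multiply(quat_inverse(qa), qb)
        w = np.clip(dq[..., 0], -1.0, 1.0)
        v = dq[..., 1:]
        sin_half = np.linalg.norm(v, axis=-1)
        angle = 2.0 * np.arctan2(sin_half, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            axis = np.where(sin_half[..., None] > 1e-12, v / sin_half[..., None], 0.0)
        return axis * (angle / step)[..., None]

    if n >= 3:
        omega[1:-1] = rate(q[:-2], q[2:], 2.0 * dt)
    if n >= 2:
        omega[0] = rate(q[0], q[1], dt)
        omega[-1] = rate(q[-2], q[-1], dt)
    return omega


def corrupt_to_imu(
    truth: dict[str, OrientationSeries],
    profile: SubjectProfile,
    rng: np.random.Generator | None = None,
) -> dict[str, InertialRecording]:
    """Turn ground-truth segment orientations into noisy virtual IMU streams.

    Per sensor: compose the segment orientation with the (misaligned) mounting
    rotation, walk the heading, then synthesize the gyroscope by finite
    differencing the corrupted orientation and the accelerometer by mapping
    gravity into the corrupted case frame (linear acceleration is omitted).
    Reproducible given the generator (defaults to one seeded from the
    profile).
    """
    rng = rng if rng is not None else np.random.default_rng(profile.seed)
    out = {}
    for seg in SEGMENTS:
        series = truth[seg]
        n = len(series)
        dt = series.dt if n > 1 else 1.0
        mount = quat_multiply(
            NOMINAL_MOUNT, profile.mounting_misalignment.get(seg, quat_identity())
        )
        q_sensor = quat_multiply(series.q, mount)
        if profile.heading_drift_rate > 0 and n > 1:
            steps = rng.normal(0.0, profile.heading_drift_rate * np.sqrt(dt), n)
            steps[0] = 0.0
            heading = np.cumsum(steps)
            q_sensor = quat_multiply(quat_from_axis_angle(_Z, heading), q_sensor)
        gyro = _body_rates(q_sensor, dt)
        accel = quat_rotate_vector(quat_inverse(q_sensor), GRAVITY)
        if profile.gyro_noise_sd > 0:
            gyro = gyro + rng.normal(0.0, profile.gyro_noise_sd, (n, 3))
        if profile.accel_noise_sd > 0:
            accel = accel + rng.normal(0.0, profile.accel_noise_sd, (n, 3))
        out[seg] = InertialRecording(series.t, q_sensor, gyro, accel)
    return out


_TRIAL_DURATIONS = {"npose_static": 3.0}


def generate_subject_trials(
    profile: SubjectProfile,
    duration_s: float = 15.0,
    reps: int = 5,
    rate_hz: float = 60.0,
    trials: tuple[str, ...] = ALL_TRIALS,
) -> dict[str, SyntheticTrial]:
    """All requested trials for one subject, deterministically from the profile seed."""
    rng = np.random.default_rng(profile.seed)
    out = {}
    for task in trials:
        dur = _TRIAL_DURATIONS.get(task, duration_s)
        angles, trunk = generate_task_trajectory(task, dur, reps, rate_hz, profile)
        is_npose = task == "npose_static"
        orientations = forward_kinematics(angles, trunk, profile, posture_error=is_npose)
        if is_npose:
            # the recorded truth includes the imperfect posture
            angles = elbow_angles(orientations["upper_arm"], orientations["lower_arm"])
        imu = corrupt_to_imu(orientations, profile, rng)
        out[task] = SyntheticTrial(
            task=task,
            truth_angles=angles,
            truth_orientations=orientations,
            imu_streams=imu,
            profile=profile,
        )
    return out


#: Study-condition parameter ranges for sampling subject profiles.
DEFAULT_PROFILE_RANGES: dict = {
    "carrying_baseline_deg": (8.0, 16.0),
    "carrying_span_deg": (5.0, 15.0),
    "carrying_shapes": ("linear", "sinusoidal"),
    "mounting_misalignment_deg": (5.0, 10.0),
    "npose_posture_error_deg": (3.0, 10.0),
    "gyro_noise_sd": 0.02,
    "accel_noise_sd": 0.2,
    "heading_drift_rate": 0.05,
}

#: Idealized conditions: perfect mounting, posture and sensors, and a
#: vanishing carrying angle (the N-pose method inherits the arm frames from
#: the trunk, so any resting carrying angle appears as an apparent error even
#: with perfect instruments) — every calibration method should be exact here.
ZERO_CORRUPTION_RANGES: dict = {
    "carrying_baseline_deg": (0.0, 0.0),
    "carrying_span_deg": (0.0, 0.0),
    "carrying_shapes": ("linear",),
    "mounting_misalignment_deg": (0.0, 0.0),
    "npose_posture_error_deg": (0.0, 0.0),
    "gyro_noise_sd": 0.0,
    "accel_noise_sd": 0.0,
    "heading_drift_rate": 0.0,
}


def _random_rotation(rng: np.random.Generator, magnitude_deg: float) -> np.ndarray:
    if magnitude_deg == 0.0:
        return quat_identity()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return quat_from_axis_angle(axis, magnitude_deg)


def sample_profile(rng: np.random.Generator, ranges: dict | None = None, seed: int = 0) -> SubjectProfile:
    """Draw one subject profile from the configured parameter ranges."""
    r = dict(DEFAULT_PROFILE_RANGES)
    r.update(ranges or {})
    lo, hi = r["carrying_baseline_deg"]
    baseline = rng.uniform(lo, hi)
    lo, hi = r["carrying_span_deg"]
    span = rng.uniform(lo, hi)
    shape = r["carrying_shapes"][rng.integers(len(r["carrying_shapes"]))]
    lo, hi = r["mounting_misalignment_deg"]
    mount = {seg: _random_rotation(rng, rng.uniform(lo, hi)) for seg in SEGMENTS}
    lo, hi = r["npose_posture_error_deg"]
    posture = {seg: _random_rotation(rng, rng.uniform(lo, hi)) for seg in SEGMENTS}
    return SubjectProfile(
        carrying_baseline_deg=float(baseline),
        carrying_span_deg=float(span),
        carrying_shape=shape,
        mounting_misalignment=mount,
        npose_posture_error=posture,
        gyro_noise_sd=float(r["gyro_noise_sd"]),
        accel_noise_sd=float(r["accel_noise_sd"]),
        heading_drift_rate=float(r["heading_drift_rate"]),
        seed=seed,
    )


def generate_study(
    n_subjects: int = 13,
    seed: int = 0,
    config: dict | None = None,
    duration_s: float = 15.0,
    reps: int = 5,
    rate_hz: float = 60.0,
    trials: tuple[str, ...] = ALL_TRIALS,
) -> dict[str, dict[str, SyntheticTrial]]:
    """Profiles and all trials for a cohort; deterministic given the seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    study = {}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sub_seed = int(rng.integers(2**31 - 1))
        profile = sample_profile(rng, config, seed=sub_seed)
        study[f"S{i + 1:02d}"] = generate_subject_trials(
            profile, duration_s=duration_s, reps=reps, rate_hz=rate_hz, trials=trials
        )
    return study
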