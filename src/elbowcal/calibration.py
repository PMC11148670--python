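"""Sensor-to-segment calibration: N-pose, functional and manual alignment.

Each method estimates, per arm segment, the fixed calibration quaternion
``q0`` (``sensor <- segment``) that converts the runtime ``global <- sensor``
orientation stream into ``global <- segment`` (see
:func:`elbowcal.kinematics.apply_calibration`).

* **N-Pose (NP)** — the subject stands still, arms straight alongside the
  body. The thorax anatomical frame is built from the gravity vector (cranial)
  and the thorax sensor's forward axis; both arm segment frames are inherited
  from that thorax frame, so the result depends solely on the trunk sensor's
  orientation and gravity.
* **Functional (FC)** — the elbow flexion/extension and pronation/supination
  hinge axes are extracted from the gyroscope streams of two prescribed
  single-plane movements and combined with a gravity / vertical reference into
  segment frames by cross-product construction.
* **Manual alignment (MA)** — the sensors are assumed mounted so their case
  axes coincide with the anatomy; ``q0`` reduces to a fixed axis permutation
  (segment X, Y, Z = sensor -y, x, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotations import (
    frame_from_axes,
    matrix_to_quat,
    quat_angle_deg,
    quat_inverse,
    quat_mean,
    quat_multiply,
    quat_rotate_vector,
)
from .series import InertialRecording

__all__ = [
    "CalibrationError",
    "InsufficientMotionError",
    "StillnessError",
    "JointAxisEstimate",
    "CalibrationResult",
    "estimate_hinge_axis",
    "translate_axis",
    "calibrate_npose",
    "calibrate_functional",
    "calibrate_manual",
    "SENSOR_FORWARD",
    "MANUAL_ALIGNMENT_MATRIX",
]

#: Sensor-case direction that points anteriorly when mounted as prescribed
#: (the sensor's -y axis faces forward on every segment).
SENSOR_FORWARD = np.array([0.0, -1.0, 0.0])

#: Segment axes expressed in sensor coordinates under perfect manual mounting:
#: columns are (X=forward, Y=cranial, Z=lateral) = (-sensor_y, sensor_x, sensor_z).
MANUAL_ALIGNMENT_MATRIX = np.array(
    [
        [0.0, 1.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
    ]
)

MIN_PEAK_GYRO = 0.3  # rad/s; below this the movement cannot anchor an axis
MIN_MOTION_DURATION = 2.0  # s
MAX_RESIDUAL_RATIO = 0.5  # off-axis energy fraction above which the fit is rejected
STILLNESS_SPREAD_DEG = 2.0  # orientation spread allowed in a static window
GRAVITY_TILT_WARN_DEG = 10.0


class CalibrationError(ValueError):
    """Base class for calibration failures."""


class InsufficientMotionError(CalibrationError):
    """Movement too slow/short (or absent) to identify a rotation axis."""


class StillnessError(CalibrationError):
    """A supposedly static recording contains too much motion."""


@dataclass
class JointAxisEstimate:
    """A hinge axis in the measuring sensor's frame.

    ``residual_ratio`` is the fraction of gyroscope energy off the fitted
    axis (0 for a perfect single-plane movement).
    """

    axis: np.ndarray
    residual_ratio: float
    sign_convention: str = "first-lobe-positive"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if not 0.0 <= self.residual_ratio <= 1.0:
            raise ValueError("residual_ratio must lie in [0, 1]")


@dataclass
class CalibrationResult:
    method: str  # "NP", "FC" or "MA"
    q0_upper_arm: np.ndarray
    q0_lower_arm: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in {"NP", "FC", "MA"}:
            raise ValueError(f"unknown calibration method {self.method!r}")
        for name in ("q0_upper_arm", "q0_lower_arm"):
            q = np.asarray(getattr(self, name), dtype=float)
            if q.shape != (4,) or abs(np.linalg.norm(q) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit quaternion of shape (4,)")
            setattr(self, name, q)


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x
    kernel = np.ones(win) / win
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")
    return out[pad : pad + x.size]


def estimate_hinge_axis(rec: InertialRecording, channel: str = "gyro") -> JointAxisEstimate:
    """Dominant rotation axis of an oscillatory single-plane movement.

    The axis is the first right-singular vector of the raw (uncentered)
    ``(n, 3)`` gyroscope matrix; hinge oscillation reverses sign across cycles
    so centering is unnecessary. The sign is fixed so that the first movement
    lobe projects positively onto the axis — under the calibration protocols
    the movement starts with flexion (respectively pronation), which makes the
    returned axis the anatomical +Z (respectively +Y) direction.
    """
    if channel != "gyro":
        raise ValueError("only gyroscope-based axis estimation is supported")
    g = rec.gyro
    if rec.duration < MIN_MOTION_DURATION:
        raise InsufficientMotionError(
            f"recording spans {rec.duration:.2f} s < {MIN_MOTION_DURATION} s"
        )
    speed = np.linalg.norm(g, axis=1)
    if speed.max() < MIN_PEAK_GYRO:
        raise InsufficientMotionError(
            f"peak angular speed {speed.max():.3f} rad/s < {MIN_PEAK_GYRO} rad/s"
        )
    _, s, vt = np.linalg.svd(g, full_matrices=False)
    total = float(np.sum(s**2))
    if total < 1e-12 or s[0] < 1e-9:
        raise InsufficientMotionError("gyroscope matrix is rank deficient")
    axis = vt[0]
    residual = 1.0 - float(s[0] ** 2) / total
    # sign: make the first significant lobe of the axis projection positive
    proj = g @ axis
    win = max(1, int(round(0.1 / rec.dt))) if np.isfinite(rec.dt) else 1
    smooth = _moving_average(proj, win)
    thresh = 0.3 * np.max(np.abs(smooth))
    idx = np.argmax(np.abs(smooth) > thresh)
    if smooth[idx] < 0:
        axis = -axis
    return JointAxisEstimate(axis=axis, residual_ratio=residual)


def translate_axis(axis_in_source, q_source: np.ndarray, q_target: np.ndarray) -> np.ndarray:
    """Re-express an axis from one sensor's frame in another's, via global.

    Both quaternions must refer to the same instant (or a common window
    average); the rotation preserves the unit norm.
    """
    axis = np.asarray(axis_in_source, dtype=float)
    axis = axis / np.linalg.norm(axis)
    in_global = quat_rotate_vector(q_source, axis)
    return quat_rotate_vector(quat_inverse(q_target), in_global)


def _middle_window(rec: InertialRecording) -> InertialRecording:
    n = len(rec)
    return rec.window(n // 4, n - n // 4) if n >= 8 else rec


def _stillness_spread_deg(q: np.ndarray) -> float:
    mean = quat_mean(q)
    return float(np.max(quat_angle_deg(q, mean)))


def calibrate_npose(
    static: dict[str, InertialRecording], gravity_up=(0.0, 0.0, 1.0)
) -> CalibrationResult:
    """Static N-pose calibration against the trunk sensor and gravity.

    The thorax anatomical frame takes ``gravity_up`` as its cranial (Y) axis
    and the thorax sensor's forward direction, orthogonalized against it, as
    the anterior (X) axis. Both arm segments inherit this thorax frame at the
    calibration instant, so each segment's ``q0`` is the window-mean sensor
    orientation inverted, composed with the thorax frame.

    ``static`` must map ``{"thorax", "upper_arm", "lower_arm"}`` to recordings
    of the same still pose; the middle 50% of each window is used.
    """
    required = {"thorax", "upper_arm", "lower_arm"}
    missing = required - static.keys()
    if missing:
        raise CalibrationError(f"missing static recordings for segments: {sorted(missing)}")
    gravity_up = np.asarray(gravity_up, dtype=float)
    gravity_up = gravity_up / np.linalg.norm(gravity_up)

    windows = {seg: _middle_window(rec) for seg, rec in static.items()}
    diagnostics: dict[str, float] = {}
    means: dict[str, np.ndarray] = {}
    for seg, win in windows.items():
        if win.duration < 0.5:
            raise StillnessError(f"{seg}: static window shorter than 0.5 s")
        spread = _stillness_spread_deg(win.q)
        diagnostics[f"stillness_spread_deg_{seg}"] = spread
        if spread > STILLNESS_SPREAD_DEG:
            raise StillnessError(
                f"{seg}: orientation spread {spread:.2f} deg exceeds "
                f"{STILLNESS_SPREAD_DEG} deg in the static window"
            )
        means[seg] = quat_mean(win.q)
        accel_mean = win.accel.mean(axis=0)
        if np.linalg.norm(accel_mean) > 1e-9:
            accel_global = quat_rotate_vector(means[seg], accel_mean / np.linalg.norm(accel_mean))
            tilt = np.degrees(np.arccos(np.clip(accel_global @ gravity_up, -1.0, 1.0)))
            diagnostics[f"gravity_tilt_deg_{seg}"] = float(tilt)
            if tilt > GRAVITY_TILT_WARN_DEG:
                diagnostics[f"gravity_tilt_warning_{seg}"] = 1.0

    forward_global = quat_rotate_vector(means["thorax"], SENSOR_FORWARD)
    thorax_frame = frame_from_axes(gravity_up, forward_global, roles=("y", "x"))
    q_frame = matrix_to_quat(thorax_frame)
    q0 = {
        seg: quat_multiply(quat_inverse(means[seg]), q_frame)
        for seg in ("upper_arm", "lower_arm")
    }
    return CalibrationResult(
        method="NP",
        q0_upper_arm=q0["upper_arm"],
        q0_lower_arm=q0["lower_arm"],
        diagnostics=diagnostics,
    )


def calibrate_functional(
    fe_ua: InertialRecording, fe_la: InertialRecording, ps_la: InertialRecording
) -> CalibrationResult:
    """Functional calibration from elbow flexion and pronation recordings.

    Upper arm: the flexion hinge axis is estimated from the *lower-arm*
    gyroscope during the flexion movement (the olecranon is supported, so the
    forearm carries the hinge rotation) and translated into the upper-arm
    sensor frame via the window-mean orientations. It takes the lateral (Z)
    role; the window-mean upper-arm accelerometer direction — gravity, i.e.
    cranial while the upper arm hangs vertically — is the secondary (Y) axis.

    Lower arm: the pronation hinge axis from the lower-arm gyroscope is the
    forearm longitudinal (Y) axis. The movement is performed with the elbow
    flexed 90 degrees, where the global vertical, mapped per sample into the
    lower-arm sensor frame and averaged, points along the anatomical anterior
    (X) axis of the forearm; it serves as the secondary axis.
    """
    est_fe = estimate_hinge_axis(fe_la)
    est_ps = estimate_hinge_axis(ps_la)
    diagnostics = {
        "fe_axis_residual_ratio": est_fe.residual_ratio,
        "ps_axis_residual_ratio": est_ps.residual_ratio,
    }
    for name, est in (("flexion", est_fe), ("pronation", est_ps)):
        if est.residual_ratio > MAX_RESIDUAL_RATIO:
            raise CalibrationError(
                f"{name} movement is not single-plane: off-axis energy "
                f"{est.residual_ratio:.2f} > {MAX_RESIDUAL_RATIO}"
            )

    # upper arm
    axis_ua = translate_axis(est_fe.axis, quat_mean(fe_la.q), quat_mean(fe_ua.q))
    accel_mean = fe_ua.accel.mean(axis=0)
    if np.linalg.norm(accel_mean) < 1e-9:
        raise CalibrationError("upper-arm accelerometer mean is zero; no vertical reference")
    frame_ua = frame_from_axes(axis_ua, accel_mean, roles=("z", "y"))
    q0_ua = matrix_to_quat(frame_ua)

    # lower arm
    vertical = quat_rotate_vector(quat_inverse(ps_la.q), np.array([0.0, 0.0, 1.0]))
    vertical = vertical.mean(axis=0)
    if np.linalg.norm(vertical) < 1e-9:
        raise CalibrationError("vertical reference vanished in the pronation window")
    frame_la = frame_from_axes(est_ps.axis, vertical, roles=("y", "x"))
    q0_la = matrix_to_quat(frame_la)

    return CalibrationResult(
        method="FC", q0_upper_arm=q0_ua, q0_lower_arm=q0_la, diagnostics=diagnostics
    )


def calibrate_manual() -> CalibrationResult:
    """Manual-alignment calibration: the fixed mounting-prescription permutation.

    Constant by construction and identical for both segments; see
    :data:`MANUAL_ALIGNMENT_MATRIX`.
    """
    q0 = matrix_to_quat(MANUAL_ALIGNMENT_MATRIX)
    return CalibrationResult(method="MA", q0_upper_arm=q0, q0_lower_arm=q0.copy())
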