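"""From calibrated segment orientations to 3-DOF elbow joint angles.

The runtime chain is the quaternion composition

    q_global<-segment = q_global<-sensor (x) q0,

where ``q0`` (the calibration quaternion, ``sensor <- segment``) comes from one
of the methods in :mod:`elbowcal.calibration`. The elbow angle triple is the
intrinsic Z-X'-Y'' factorization of the humerus-to-forearm relative rotation:
flexion about Z (lateral), carrying angle about the floating X, pronation about
Y (longitudinal).
"""

from __future__ import annotations

import numpy as np

from .rotations import (
    GIMBAL_GUARD_DEG,
    euler_zxy_angles,
    quat_inverse,
    quat_multiply,
    quat_to_matrix,
)
from .series import JointAngleSeries, OrientationSeries

__all__ = ["apply_calibration", "elbow_angles"]


def apply_calibration(runtime: OrientationSeries, q0: np.ndarray) -> OrientationSeries:
    """Right-multiply each global<-sensor sample by the calibration quaternion.

    Returns the global<-segment orientation stream.
    """
    q0 = np.asarray(q0, dtype=float)
    if q0.shape != (4,):
        raise ValueError("q0 must be a single quaternion of shape (4,)")
    return OrientationSeries(runtime.t, quat_multiply(runtime.q, q0))


def _unwrap_deg(angles: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(angles)))


def elbow_angles(upper_arm: OrientationSeries, lower_arm: OrientationSeries) -> JointAngleSeries:
    """3-DOF elbow angles from time-aligned segment orientation streams.

    Per sample the relative rotation ``inverse(q_upper) (x) q_lower`` is
    decomposed in the intrinsic ZXY order. Flexion and pronation are phase
    unwrapped along time; the carrying angle lives in [-90, 90] by
    construction. Samples whose carrying angle comes within 0.5 deg of +/-90
    are flagged (gimbal proximity), not dropped.
    """
    if len(upper_arm) != len(lower_arm) or not np.allclose(upper_arm.t, lower_arm.t):
        raise ValueError("upper-arm and lower-arm series must share timestamps")
    q_rel = quat_multiply(quat_inverse(upper_arm.q), lower_arm.q)
    angles = euler_zxy_angles(quat_to_matrix(q_rel))
    flexion = _unwrap_deg(angles[:, 0])
    carrying = angles[:, 1]
    pronation = _unwrap_deg(angles[:, 2])
    flags = np.abs(np.abs(carrying) - 90.0) < GIMBAL_GUARD_DEG
    return JointAngleSeries(upper_arm.t, flexion, carrying, pronation, flags)
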