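"""Quaternion and rotation-matrix algebra for segment kinematics.

Conventions used throughout the package:

* Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, and passive: a
  quaternion attached to a sensor or segment represents the rotation
  ``global <- local``, i.e. its rotation matrix has the local frame's axes as
  columns, expressed in the global frame.
* ``q`` and ``-q`` encode the same rotation; comparison helpers treat them as
  equal.
* The elbow joint angle sequence is intrinsic Z-X'-Y'' (the ISB elbow
  convention): first rotation about the segment Z (lateral) axis is
  flexion(+)/extension(-), the rotation about the floating X axis is the
  carrying angle, and the final rotation about Y (longitudinal) is
  pronation(+)/supination(-).
* Public angle APIs are in degrees; radians are internal.

All functions accept single quaternions of shape ``(4,)`` or stacked series of
shape ``(n, 4)`` (likewise ``(3, 3)`` / ``(n, 3, 3)`` for matrices) and
broadcast accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EulerZXY",
    "DegenerateFrameError",
    "quat_identity",
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_inverse",
    "quat_from_axis_angle",
    "quat_rotate_vector",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_angle_deg",
    "quat_allclose",
    "quat_mean",
    "frame_from_axes",
    "euler_zxy_compose",
    "euler_zxy_decompose",
    "GIMBAL_GUARD_DEG",
]

#: Samples whose carrying angle comes within this margin of +/-90 deg are
#: flagged as gimbal-proximal (the decomposition is still returned).
GIMBAL_GUARD_DEG = 0.5

_UNIT_TOL = 1e-9


class DegenerateFrameError(ValueError):
    """Raised when a frame is requested from near-parallel axis pairs."""


@dataclass(frozen=True)
class EulerZXY:
    """Intrinsic Z-X'-Y'' angles in degrees.

    ``alpha_deg`` is the first rotation (about Z: flexion), ``gamma_deg`` the
    second (about the floating X: carrying angle, confined to [-90, 90]),
    ``beta_deg`` the third (about Y: pronation).
    """

    alpha_deg: float
    gamma_deg: float
    beta_deg: float


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def _check_finite(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite quaternion components")
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = _check_finite(q)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero quaternion cannot be normalized")
    return q / norm


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a (x) b``, renormalized.

    Composition order matches the matrix product: the rotation matrix of the
    result equals ``quat_to_matrix(a) @ quat_to_matrix(b)``.
    """
    a = _check_finite(a)
    b = _check_finite(b)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    return quat_normalize(out)

def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = _check_finite(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_inverse(q: np.ndarray) -> np.ndarray:
    """Inverse rotation; for the unit quaternions used here, the conjugate."""
    return quat_conjugate(quat_normalize(q))


def quat_from_axis_angle(axis, angle_deg) -> np.ndarray:
    """Unit quaternion for rotation(s) of ``angle_deg`` about ``axis``.

    ``angle_deg`` may be a scalar or an ``(n,)`` array (fixed axis, varying
    angle), in which case an ``(n, 4)`` series is returned.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = np.deg2rad(np.asarray(angle_deg, dtype=float)) / 2.0
    w = np.cos(half)[..., None]
    xyz = np.sin(half)[..., None] * axis
    return np.concatenate([w, xyz], axis=-1)


def quat_rotate_vector(q: np.ndarray, v) -> np.ndarray:
    """Rotate vector(s) ``v`` (local coords) into the parent frame of ``q``."""
    q = quat_normalize(q)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    q = quat_normalize(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    m = np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=-2,
    )
    return m


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """Convert rotation matrices to scalar-first unit quaternions.

    Uses Shepperd's branch selection for numerical robustness; the returned
    quaternion has non-negative scalar part.
    """
    m = np.asarray(m, dtype=float)
    single = m.ndim == 2
    m = m.reshape(-1, 3, 3)
    tr = np.einsum("nii->n", m)
    q = np.empty((m.shape[0], 4))
    # branch on the largest of (trace, m00, m11, m22)
    choices = np.stack([tr, m[:, 0, 0], m[:, 1, 1], m[:, 2, 2]], axis=1)
    branch = np.argmax(choices, axis=1)
    for i in range(m.shape[0]):
        a = m[i]
        if branch[i] == 0:
            s = np.sqrt(tr[i] + 1.0) * 2.0
            q[i] = [0.25 * s, (a[2, 1] - a[1, 2]) / s, (a[0, 2] - a[2, 0]) / s, (a[1, 0] - a[0, 1]) / s]
        elif branch[i] == 1:
            s = np.sqrt(1.0 + a[0, 0] - a[1, 1] - a[2, 2]) * 2.0
            q[i] = [(a[2, 1] - a[1, 2]) / s, 0.25 * s, (a[0, 1] + a[1, 0]) / s, (a[0, 2] + a[2, 0]) / s]
        elif branch[i] == 2:
            s = np.sqrt(1.0 - a[0, 0] + a[1, 1] - a[2, 2]) * 2.0
            q[i] = [(a[0, 2] - a[2, 0]) / s, (a[0, 1] + a[1, 0]) / s, 0.25 * s, (a[1, 2] + a[2, 1]) / s]
        else:
            s = np.sqrt(1.0 - a[0, 0] - a[1, 1] + a[2, 2]) * 2.0
            q[i] = [(a[1, 0] - a[0, 1]) / s, (a[0, 2] + a[2, 0]) / s, (a[1, 2] + a[2, 1]) / s, 0.25 * s]
    sign = np.where(q[:, :1] < 0, -1.0, 1.0)
    q = quat_normalize(q * sign)
    return q[0] if single else q


def quat_angle_deg(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Geodesic angle (deg) of ``a`` relative to ``b`` (identity if omitted)."""
    if b is not None:
        a = quat_multiply(quat_inverse(b), a)
    else:
        a = quat_normalize(a)
    w = np.clip(np.abs(a[..., 0]), -1.0, 1.0)
    return np.degrees(2.0 * np.arccos(w))


def quat_allclose(a: np.ndarray, b: np.ndarray, atol_deg: float = 1e-7) -> bool:
    """Equality of rotations, blind to the q / -q sign ambiguity."""
    return bool(np.all(quat_angle_deg(np.atleast_2d(a), np.atleast_2d(b)) <= atol_deg))


def quat_mean(q: np.ndarray) -> np.ndarray:
    """Chordal mean of a quaternion series (eigenvector of sum q q^T)."""
    q = quat_normalize(np.atleast_2d(q))
    a = q.T @ q
    _, vecs = np.linalg.eigh(a)
    mean = vecs[:, -1]
    if mean[0] < 0:
        mean = -mean
    return mean


_ROLES = ("x", "y", "z")
# role r is the cross product of roles _CYCLE[r] (right-handed axes)
_CYCLE = {"x": ("y", "z"), "y": ("z", "x"), "z": ("x", "y")}


def frame_from_axes(primary, secondary, roles: tuple[str, str]) -> np.ndarray:
    """Build a right-handed orthonormal frame from a primary/secondary axis pair.

    ``roles`` names the columns the two inputs occupy, e.g. ``("z", "y")``
    assigns the primary axis to the Z (lateral) column and uses the secondary
    to fix the Y (longitudinal) column. The primary column is kept exactly;
    the secondary is orthogonalized against it via two cross products, so only
    its component orthogonal to the primary matters.

    Raises :class:`DegenerateFrameError` when the axes are within 1 degree of
    parallel.
    """
    p_role, s_role = roles
    if p_role not in _ROLES or s_role not in _ROLES or p_role == s_role:
        raise ValueError(f"roles must be two distinct axis labels, got {roles!r}")
    p = np.asarray(primary, dtype=float)
    s = np.asarray(secondary, dtype=float)
    p = p / np.linalg.norm(p)
    s_norm = np.linalg.norm(s)
    if s_norm < 1e-12:
        raise DegenerateFrameError("secondary axis has zero length")
    s_unit = s / s_norm
    angle = np.degrees(np.arcsin(np.clip(np.linalg.norm(np.cross(p, s_unit)), 0.0, 1.0)))
    if angle < 1.0:
        raise DegenerateFrameError(
            f"primary and secondary axes are {angle:.3f} deg from parallel (< 1 deg)"
        )
    (t_role,) = set(_ROLES) - {p_role, s_role}
    cols: dict[str, np.ndarray] = {p_role: p}
    a_role, b_role = _CYCLE[t_role]
    if a_role == s_role:
        t = np.cross(s_unit, p)
    else:
        t = np.cross(p, s_unit)
    cols[t_role] = t / np.linalg.norm(t)
    a_role, b_role = _CYCLE[s_role]
    cols[s_role] = np.cross(cols[a_role], cols[b_role])
    return np.stack([cols["x"], cols["y"], cols["z"]], axis=-1)


def euler_zxy_compose(e: EulerZXY | tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix of intrinsic Z-X'-Y'' angles (degrees)."""
    if isinstance(e, EulerZXY):
        alpha, gamma, beta = e.alpha_deg, e.gamma_deg, e.beta_deg
    else:
        alpha, gamma, beta = e
    a, g, b = np.deg2rad([alpha, gamma, beta])
    ca, sa = np.cos(a), np.sin(a)
    cg, sg = np.cos(g), np.sin(g)
    cb, sb = np.cos(b), np.sin(b)
    return np.array(
        [
            [ca * cb - sa * sg * sb, -sa * cg, ca * sb + sa * sg * cb],
            [sa * cb + ca * sg * sb, ca * cg, sa * sb - ca * sg * cb],
            [-cg * sb, sg, cg * cb],
        ]
    )


def euler_zxy_angles(m: np.ndarray) -> np.ndarray:
    """Vectorized Z-X'-Y'' factorization; returns ``(..., 3)`` of (alpha, gamma, beta) deg."""
    m = np.asarray(m, dtype=float)
    gamma = np.arcsin(np.clip(m[..., 2, 1], -1.0, 1.0))
    alpha = np.arctan2(-m[..., 0, 1], m[..., 1, 1])
    beta = np.arctan2(-m[..., 2, 0], m[..., 2, 2])
    return np.degrees(np.stack([alpha, gamma, beta], axis=-1))


def euler_zxy_decompose(m: np.ndarray) -> tuple[EulerZXY, bool]:
    """Decompose one rotation matrix; returns angles and a gimbal-proximity flag.

    Near ``gamma = +/-90 deg`` (within :data:`GIMBAL_GUARD_DEG`) the first and
    third axes align and the split between alpha and beta is ill-conditioned;
    the sample is flagged rather than rejected.
    """
    angles = euler_zxy_angles(np.asarray(m, dtype=float))
    alpha, gamma, beta = (float(v) for v in angles)
    flagged = abs(abs(gamma) - 90.0) < GIMBAL_GUARD_DEG
    return EulerZXY(alpha_deg=alpha, gamma_deg=gamma, beta_deg=beta), flagged
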