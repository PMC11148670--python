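"""Time-series containers: orientation streams, inertial recordings, joint angles.

These are thin, validated wrappers around numpy arrays. The quaternion columns
always hold the passive ``global <- sensor`` (or ``global <- segment``)
rotation, scalar first; see :mod:`elbowcal.rotations` for the conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rotations import quat_mean, quat_normalize

__all__ = ["OrientationSeries", "InertialRecording", "JointAngleSeries"]

#: Maximum tolerated relative jitter of the sampling interval.
MAX_JITTER = 0.2


def _validate_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("timestamps must be a non-empty 1-D array")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        med = np.median(dt)
        if np.any(np.abs(dt - med) > MAX_JITTER * med):
            raise ValueError("sampling interval jitter exceeds 20% of the median")
    return t


@dataclass
class OrientationSeries:
    """Timestamps plus unit quaternions (global <- sensor/segment)."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.t = _validate_time(self.t)
        q = np.asarray(self.q, dtype=float)
        if q.shape != (self.t.size, 4):
            raise ValueError(f"quaternion array must be (n, 4), got {q.shape}")
        self.q = quat_normalize(q)

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if len(self) > 1 else np.nan

    def mean_quaternion(self) -> np.ndarray:
        return quat_mean(self.q)

    def window(self, start: int, end: int) -> "OrientationSeries":
        return OrientationSeries(self.t[start:end], self.q[start:end])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "qw": self.q[:, 0], "qx": self.q[:, 1], "qy": self.q[:, 2], "qz": self.q[:, 3]}
        )


@dataclass
class InertialRecording:
    """Orientation stream plus synchronized gyroscope (rad/s) and accelerometer (m/s^2)."""

    t: np.ndarray
    q: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.t = _validate_time(self.t)
        n = self.t.size
        q = np.asarray(self.q, dtype=float)
        if q.shape != (n, 4):
            raise ValueError(f"quaternion array must be ({n}, 4), got {q.shape}")
        self.q = quat_normalize(q)
        for name in ("gyro", "accel"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} array must be ({n}, 3), got {arr.shape}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if len(self) > 1 else np.nan

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def orientation(self) -> OrientationSeries:
        return OrientationSeries(self.t, self.q)

    def window(self, start: int, end: int) -> "InertialRecording":
        return InertialRecording(
            self.t[start:end], self.q[start:end], self.gyro[start:end], self.accel[start:end]
        )

    def to_frame(self) -> pd.DataFrame:
        df = OrientationSeries(self.t, self.q).to_frame()
        df[["gx", "gy", "gz"]] = self.gyro
        df[["ax", "ay", "az"]] = self.accel
        return df


@dataclass
class JointAngleSeries:
    """Per-sample elbow angles in degrees with gimbal-proximity flags."""

    t: np.ndarray
    flexion_deg: np.ndarray
    carrying_deg: np.ndarray
    pronation_deg: np.ndarray
    gimbal_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = _validate_time(self.t)
        n = self.t.size
        for name in ("flexion_deg", "carrying_deg", "pronation_deg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must be ({n},), got {arr.shape}")
            setattr(self, name, arr)
        if self.gimbal_flags is None:
            self.gimbal_flags = np.zeros(n, dtype=bool)
        else:
            self.gimbal_flags = np.asarray(self.gimbal_flags, dtype=bool)
            if self.gimbal_flags.shape != (n,):
                raise ValueError("gimbal_flags length mismatch")

    def __len__(self) -> int:
        return self.t.size

    def axis(self, name: str) -> np.ndarray:
        """Angle samples for an axis label: 'flexion', 'carrying' or 'pronation'."""
        try:
            return getattr(self, f"{name}_deg")
        except AttributeError:
            raise KeyError(f"unknown axis {name!r}") from None

    def window(self, start: int, end: int) -> "JointAngleSeries":
        return JointAngleSeries(
            self.t[start:end],
            self.flexion_deg[start:end],
            self.carrying_deg[start:end],
            self.pronation_deg[start:end],
            self.gimbal_flags[start:end],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "flexion_deg": self.flexion_deg,
                "carrying_deg": self.carrying_deg,
                "pronation_deg": self.pronation_deg,
                "gimbal_flag": self.gimbal_flags.astype(int),
            }
        )
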