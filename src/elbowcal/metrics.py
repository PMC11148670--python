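"""Per-repetition joint-angle accuracy metrics and repetition segmentation.

Reference (optical stand-in) and test (IMU) angle series are compared within
each movement repetition on three metrics, all in degrees:

* ``rom_error`` — (max - min) of the reference minus (max - min) of the test:
  the range-of-motion discrepancy. Invariant to constant shifts of either
  series.
* ``rmse`` — root-mean-square of the difference between the two series after
  each has been demeaned by its *own* within-repetition mean. The demeaning
  makes it a pure waveform-shape error, insensitive to any constant offset.
* ``offset`` — mean(reference) - mean(test): the constant bias the demeaning
  removed from the RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .series import JointAngleSeries

__all__ = [
    "RepetitionWindow",
    "MetricRecord",
    "FlatSignalError",
    "segment_repetitions",
    "rom_error",
    "rmse",
    "offset",
    "compute_metrics",
    "records_to_frame",
]

AXES = ("flexion", "carrying", "pronation")
MIN_RANGE_DEG = 10.0
SMOOTH_WINDOW_S = 0.25


class FlatSignalError(ValueError):
    """The dominant axis shows too little excursion to segment repetitions."""


@dataclass(frozen=True)
class RepetitionWindow:
    """Half-open sample range [start, end) of one movement repetition."""

    start_index: int
    end_index: int
    label: int

    def __post_init__(self) -> None:
        if not self.start_index < self.end_index:
            raise ValueError("repetition window must satisfy start < end")


@dataclass(frozen=True)
class MetricRecord:
    subject: str
    calibration: str
    task: str
    axis: str
    repetition: int
    rom_error_deg: float
    rmse_deg: float
    offset_deg: float

    def __post_init__(self) -> None:
        if self.rmse_deg < 0:
            raise ValueError("rmse_deg must be non-negative")


def _smooth(x: np.ndarray, dt: float) -> np.ndarray:
    win = max(1, int(round(SMOOTH_WINDOW_S / dt))) if np.isfinite(dt) and dt > 0 else 1
    if win <= 1:
        return x
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, np.ones(win) / win, mode="same")[pad : pad + x.size]


def segment_repetitions(
    angles: JointAngleSeries, dominant_axis: str, expected: int
) -> list[RepetitionWindow]:
    """Cut a trial into repetitions at the minima of the dominant-axis signal.

    The dominant-axis angle is smoothed with a 0.25 s moving average; windows
    run between consecutive minima (trial start and end act as outer cuts).
    When fewer than ``expected`` full cycles exist, the windows found are
    returned with a warning; a flat signal raises :class:`FlatSignalError`.
    """
    sig = angles.axis(dominant_axis)
    n = sig.size
    if n < 2 * max(expected, 1):
        raise ValueError("series too short for the expected repetition count")
    rng = float(np.ptp(sig))
    if rng < MIN_RANGE_DEG:
        raise FlatSignalError(
            f"{dominant_axis} peak-to-peak range {rng:.1f} deg < {MIN_RANGE_DEG} deg"
        )
    smooth = _smooth(sig, angles.t[1] - angles.t[0] if n > 1 else np.nan)
    min_period = max(2, n // (2 * max(expected, 1)))
    minima, _ = find_peaks(-smooth, prominence=0.1 * rng, distance=min_period)
    cuts = [0, *minima.tolist(), n]
    cuts = sorted(set(cuts))
    # drop slivers at the edges (the signal may start/end exactly at a minimum)
    median_len = np.median(np.diff(cuts)) if len(cuts) > 1 else n
    windows = []
    for start, end in zip(cuts[:-1], cuts[1:]):
        if end - start < 0.25 * median_len:
            continue
        windows.append((start, end))
    if len(windows) != expected:
        warnings.warn(
            f"expected {expected} repetitions, found {len(windows)}",
            RuntimeWarning,
            stacklevel=2,
        )
    return [RepetitionWindow(s, e, i + 1) for i, (s, e) in enumerate(windows)]


def _check_samples(reference, test, equal_length: bool) -> tuple[np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.size == 0 or test.size == 0:
        raise ValueError("angle sample arrays must be non-empty")
    if equal_length and reference.size != test.size:
        raise ValueError("reference and test series must have equal length")
    return reference, test


def rom_error(opto, imu) -> float:
    """Range-of-motion error: ptp(reference) - ptp(test), degrees."""
    opto, imu = _check_samples(opto, imu, equal_length=False)
    return float(np.ptp(opto) - np.ptp(imu))


def rmse(opto, imu) -> float:
    """RMS of the difference between the two self-demeaned series, degrees."""
    opto, imu = _check_samples(opto, imu, equal_length=True)
    if opto.size < 2:
        raise ValueError("rmse needs at least two samples per repetition")
    d = (opto - opto.mean()) - (imu - imu.mean())
    return float(np.sqrt(np.mean(d**2)))


def offset(opto, imu) -> float:
    """Constant bias: mean(reference) - mean(test), degrees."""
    opto, imu = _check_samples(opto, imu, equal_length=False)
    return float(opto.mean() - imu.mean())


def compute_metrics(
    reference: JointAngleSeries,
    test: JointAngleSeries,
    windows: list[RepetitionWindow],
    subject: str = "",
    calibration: str = "",
    task: str = "",
) -> list[MetricRecord]:
    """One :class:`MetricRecord` per repetition window and joint axis."""
    if len(reference) != len(test) or not np.allclose(reference.t, test.t):
        raise ValueError("reference and test series must share timestamps")
    n = len(reference)
    records = []
    for w in windows:
        if not (0 <= w.start_index < w.end_index <= n):
            raise ValueError(f"window {w} out of bounds for series of length {n}")
        for axis in AXES:
            ref = reference.axis(axis)[w.start_index : w.end_index]
            tst = test.axis(axis)[w.start_index : w.end_index]
            records.append(
                MetricRecord(
                    subject=subject,
                    calibration=calibration,
                    task=task,
                    axis=axis,
                    repetition=w.label,
                    rom_error_deg=rom_error(ref, tst),
                    rmse_deg=rmse(ref, tst),
                    offset_deg=offset(ref, tst),
                )
            )
    return records


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Tidy table of metric records (one row per subject/calibration/task/axis/rep)."""
    return pd.DataFrame([r.__dict__ for r in records])
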