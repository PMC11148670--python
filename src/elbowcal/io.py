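"""CSV/JSON I/O for orientation streams, joint angles, metrics and trials.

Canonical on-disk formats (all plain text):

* orientation / inertial CSV — columns ``t_s, qw, qx, qy, qz`` and optionally
  ``gx, gy, gz, ax, ay, az`` (gyro rad/s, accel m/s^2);
* joint-angle CSV — ``t_s, flexion_deg, carrying_deg, pronation_deg,
  gimbal_flag``;
* metric tables — tidy CSV from :func:`elbowcal.metrics.records_to_frame`;
* calibration result — JSON with the method tag, both quaternions and the
  diagnostics map;
* trial directories — one sub-directory per trial holding per-sensor CSVs, a
  truth-angle CSV and a ``manifest.json`` describing the task and profile.

Numeric CSV output is written with six decimal places.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .series import InertialRecording, JointAngleSeries, OrientationSeries
from .simulate import SEGMENTS, SubjectProfile, SyntheticTrial

__all__ = [
    "SchemaError",
    "load_orientation_csv",
    "save_orientation_csv",
    "load_joint_angles_csv",
    "save_joint_angles_csv",
    "save_calibration_json",
    "load_calibration_json",
    "save_trial",
    "load_trial",
    "save_study",
    "load_study",
]

ORIENTATION_COLUMNS = ["t_s", "qw", "qx", "qy", "qz"]
INERTIAL_COLUMNS = ORIENTATION_COLUMNS + ["gx", "gy", "gz", "ax", "ay", "az"]
FLOAT_FORMAT = "%.6f"
MAX_NORM_DEVIATION = 0.01


class SchemaError(ValueError):
    """A file does not match the expected column schema or content rules."""


def load_orientation_csv(path) -> OrientationSeries | InertialRecording:
    """Read an orientation or full inertial CSV, validating as it goes.

    Quaternions are renormalized; rows whose norm deviates from 1 by more
    than 1% are rejected. NaN rows and non-monotone timestamps raise
    :class:`SchemaError` naming the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[: len(ORIENTATION_COLUMNS)] != ORIENTATION_COLUMNS:
        raise SchemaError(
            f"{path}: expected leading columns {ORIENTATION_COLUMNS}, found {cols[:5]}"
        )
    has_inertial = cols[: len(INERTIAL_COLUMNS)] == INERTIAL_COLUMNS
    if not has_inertial and len(cols) > len(ORIENTATION_COLUMNS):
        raise SchemaError(f"{path}: unrecognized trailing columns {cols[5:]}")
    nan_rows = df.index[df.isna().any(axis=1)].tolist()
    if nan_rows:
        raise SchemaError(f"{path}: NaN values in rows {nan_rows[:10]}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise SchemaError(f"{path}: non-monotone timestamps at row {bad}")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(q, axis=1)
    bad_norm = np.where(np.abs(norms - 1.0) > MAX_NORM_DEVIATION)[0]
    if bad_norm.size:
        raise SchemaError(
            f"{path}: quaternion norm deviates more than 1% in rows {bad_norm[:10].tolist()}"
        )
    if has_inertial:
        return InertialRecording(
            t, q, df[["gx", "gy", "gz"]].to_numpy(float), df[["ax", "ay", "az"]].to_numpy(float)
        )
    return OrientationSeries(t, q)


def save_orientation_csv(series: OrientationSeries | InertialRecording, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def load_joint_angles_csv(path) -> JointAngleSeries:
    df = pd.read_csv(path)
    required = ["t_s", "flexion_deg", "carrying_deg", "pronation_deg"]
    if list(df.columns[:4]) != required:
        raise SchemaError(f"{path}: expected columns {required}, found {list(df.columns)[:4]}")
    flags = df["gimbal_flag"].to_numpy(bool) if "gimbal_flag" in df else None
    return JointAngleSeries(
        df["t_s"].to_numpy(float),
        df["flexion_deg"].to_numpy(float),
        df["carrying_deg"].to_numpy(float),
        df["pronation_deg"].to_numpy(float),
        flags,
    )


def save_joint_angles_csv(angles: JointAngleSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    angles.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def save_calibration_json(result: CalibrationResult, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "method": result.method,
        "q0_upper_arm": result.q0_upper_arm.tolist(),
        "q0_lower_arm": result.q0_lower_arm.tolist(),
        "diagnostics": {k: float(v) for k, v in result.diagnostics.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_calibration_json(path) -> CalibrationResult:
    data = json.loads(Path(path).read_text())
    return CalibrationResult(
        method=data["method"],
        q0_upper_arm=np.asarray(data["q0_upper_arm"], dtype=float),
        q0_lower_arm=np.asarray(data["q0_lower_arm"], dtype=float),
        diagnostics=data.get("diagnostics", {}),
    )


def _profile_to_dict(profile: SubjectProfile) -> dict:
    return {
        "carrying_baseline_deg": profile.carrying_baseline_deg,
        "carrying_span_deg": profile.carrying_span_deg,
        "carrying_shape": profile.carrying_shape,
        "mounting_misalignment": {k: v.tolist() for k, v in profile.mounting_misalignment.items()},
        "npose_posture_error": {k: v.tolist() for k, v in profile.npose_posture_error.items()},
        "gyro_noise_sd": profile.gyro_noise_sd,
        "accel_noise_sd": profile.accel_noise_sd,
        "heading_drift_rate": profile.heading_drift_rate,
        "seed": profile.seed,
    }


def _profile_from_dict(d: dict) -> SubjectProfile:
    return SubjectProfile(
        carrying_baseline_deg=d["carrying_baseline_deg"],
        carrying_span_deg=d["carrying_span_deg"],
        carrying_shape=d["carrying_shape"],
        mounting_misalignment={k: np.asarray(v) for k, v in d["mounting_misalignment"].items()},
        npose_posture_error={k: np.asarray(v) for k, v in d["npose_posture_error"].items()},
        gyro_noise_sd=d["gyro_noise_sd"],
        accel_noise_sd=d["accel_noise_sd"],
        heading_drift_rate=d["heading_drift_rate"],
        seed=d["seed"],
    )


def save_trial(trial: SyntheticTrial, directory) -> Path:
    """Write one trial as per-sensor CSVs + truth CSVs + manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for seg in SEGMENTS:
        save_orientation_csv(trial.imu_streams[seg], directory / f"imu_{seg}.csv")
        save_orientation_csv(trial.truth_orientations[seg], directory / f"truth_{seg}.csv")
    save_joint_angles_csv(trial.truth_angles, directory / "truth_angles.csv")
    manifest = {"task": trial.task, "profile": _profile_to_dict(trial.profile)}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_trial(directory) -> SyntheticTrial:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"{directory}: missing manifest.json")
    manifest = json.loads(manifest_path.read_text())
    profile = _profile_from_dict(manifest["profile"])
    imu = {}
    truth = {}
    for seg in SEGMENTS:
        rec = load_orientation_csv(directory / f"imu_{seg}.csv")
        if not isinstance(rec, InertialRecording):
            raise SchemaError(f"{directory}: imu_{seg}.csv lacks gyro/accel columns")
        imu[seg] = rec
        truth_series = load_orientation_csv(directory / f"truth_{seg}.csv")
        truth[seg] = OrientationSeries(truth_series.t, truth_series.q)
    angles = load_joint_angles_csv(directory / "truth_angles.csv")
    return SyntheticTrial(
        task=manifest["task"],
        truth_angles=angles,
        truth_orientations=truth,
        imu_streams=imu,
        profile=profile,
    )


def save_study(study: dict[str, dict[str, SyntheticTrial]], directory) -> Path:
    directory = Path(directory)
    for subject, trials in study.items():
        for task, trial in trials.items():
            save_trial(trial, directory / subject / task)
    index = {subject: sorted(trials) for subject, trials in study.items()}
    (directory / "study.json").write_text(json.dumps(index, indent=2))
    return directory


def load_study(directory) -> dict[str, dict[str, SyntheticTrial]]:
    directory = Path(directory)
    index_path = directory / "study.json"
    if not index_path.exists():
        raise SchemaError(f"{directory}: missing study.json index")
    index = json.loads(index_path.read_text())
    return {
        subject: {task: load_trial(directory / subject / task) for task in tasks}
        for subject, tasks in index.items()
    }
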