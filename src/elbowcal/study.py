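"""End-to-end study runner: simulate -> calibrate -> angles -> metrics -> ANOVA.

:func:`run_study` reproduces a full calibration-comparison experiment on
virtual subjects: each subject's calibration recordings feed the three
sensor-to-segment methods, the resulting calibration quaternions are applied
to that subject's task recordings, and the IMU-derived elbow angles are scored
against the ground-truth (optical stand-in) angles per repetition. The
per-repetition metric table then drives the three-way within-subject ANOVA.
Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .anova import AnovaEffect, effects_to_frame, rm_anova_three_way
from .calibration import (
    CalibrationResult,
    calibrate_functional,
    calibrate_manual,
    calibrate_npose,
)
from .kinematics import apply_calibration, elbow_angles
from .metrics import compute_metrics, records_to_frame, segment_repetitions
from .simulate import DOMINANT_AXIS, TASKS, SyntheticTrial

logger = logging.getLogger("elbowcal")

__all__ = ["StudyConfig", "StudyResult", "run_study", "calibrate_subject"]

CALIBRATIONS = ("NP", "FC", "MA")


@dataclass
class StudyConfig:
    """Factors, cohort size and study conditions of one synthetic experiment."""

    calibrations: tuple[str, ...] = CALIBRATIONS
    tasks: tuple[str, ...] = TASKS
    n_subjects: int = 13
    reps: int = 5
    duration_s: float = 15.0
    rate_hz: float = 60.0
    seed: int = 0
    profile_ranges: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.calibrations or not self.tasks:
            raise ValueError("calibration and task sets must be non-empty")
        unknown = set(self.calibrations) - set(CALIBRATIONS)
        if unknown:
            raise ValueError(f"unknown calibrations {sorted(unknown)}")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "output_dir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("calibrations", "tasks"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StudyResult:
    """Metric table, ANOVA effects and summary statistics of one study run."""

    config: StudyConfig
    records: pd.DataFrame
    anova: dict[str, list[AnovaEffect]]
    calibrations: dict[str, dict[str, CalibrationResult]]

    def cell_means(self) -> pd.DataFrame:
        """Repetition-averaged metrics per subject/calibration/task/axis cell."""
        return (
            self.records.groupby(["subject", "calibration", "task", "axis"], observed=True)[
                ["rom_error_deg", "rmse_deg", "offset_deg"]
            ]
            .mean()
            .reset_index()
        )

    def calibration_means(self) -> pd.DataFrame:
        """Grand mean of each metric per calibration method."""
        return (
            self.cell_means()
            .groupby("calibration", observed=True)[["rom_error_deg", "rmse_deg", "offset_deg"]]
            .mean()
        )

    def summary(self) -> str:
        lines = [
            f"Synthetic calibration study: {self.config.n_subjects} subjects, "
            f"{len(self.config.tasks)} tasks, {len(self.config.calibrations)} calibrations, "
            f"seed {self.config.seed} (config {self.config.config_hash()})",
            "",
            "Grand means per calibration (deg):",
            self.calibration_means().round(3).to_string(),
        ]
        for dv, effects in self.anova.items():
            lines += ["", f"Three-way RM-ANOVA — {dv}:",
                      effects_to_frame(effects).round(4).to_string(index=False)]
        return "\n".join(lines)

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(directory / "metrics.csv", index=False, float_format="%.6f")
        for dv, effects in self.anova.items():
            effects_to_frame(effects).to_csv(
                directory / f"anova_{dv}.csv", index=False, float_format="%.6g"
            )
        (directory / "summary.txt").write_text(self.summary() + "\n")
        return directory


def calibrate_subject(
    trials: dict[str, SyntheticTrial], methods: tuple[str, ...] = CALIBRATIONS
) -> dict[str, CalibrationResult]:
    """Run the requested calibration methods on one subject's calibration trials."""
    out: dict[str, CalibrationResult] = {}
    if "NP" in methods:
        static = trials["npose_static"].imu_streams
        out["NP"] = calibrate_npose(static)
    if "FC" in methods:
        fe = trials["fe_calibration"].imu_streams
        ps = trials["ps_calibration"].imu_streams
        out["FC"] = calibrate_functional(fe["upper_arm"], fe["lower_arm"], ps["lower_arm"])
    if "MA" in methods:
        out["MA"] = calibrate_manual()
    return out


def run_study(config: StudyConfig, study: dict | None = None) -> StudyResult:
    """Execute the full pipeline; pass ``study`` to reuse pre-generated trials."""
    logger.info(
        "study start: seed=%d subjects=%d hash=%s",
        config.seed,
        config.n_subjects,
        config.config_hash(),
    )
    if study is None:
        study = simulate.generate_study(
            n_subjects=config.n_subjects,
            seed=config.seed,
            config=config.profile_ranges,
            duration_s=config.duration_s,
            reps=config.reps,
            rate_hz=config.rate_hz,
        )
    all_records = []
    calibrations: dict[str, dict[str, CalibrationResult]] = {}
    for subject, trials in study.items():
        cals = calibrate_subject(trials, config.calibrations)
        calibrations[subject] = cals
        for task in config.tasks:
            trial = trials[task]
            reference = trial.truth_angles
            try:
                windows = segment_repetitions(reference, DOMINANT_AXIS[task], config.reps)
            except ValueError as exc:
                raise RuntimeError(f"{subject}/{task}: repetition segmentation failed") from exc
            for method, cal in cals.items():
                ua = apply_calibration(
                    trial.imu_streams["upper_arm"].orientation, cal.q0_upper_arm
                )
                la = apply_calibration(
                    trial.imu_streams["lower_arm"].orientation, cal.q0_lower_arm
                )
                imu_angles = elbow_angles(ua, la)
                records = compute_metrics(
                    reference, imu_angles, windows, subject=subject, calibration=method, task=task
                )
                all_records.extend(records)
                logger.debug("%s/%s/%s: %d records", subject, task, method, len(records))
    table = records_to_frame(all_records)
    anova = {}
    if len(config.calibrations) > 1 and len(config.tasks) > 1 and config.n_subjects > 2:
        for dv in ("rom_error", "rmse", "offset"):
            anova[dv] = rm_anova_three_way(table, dv)
    result = StudyResult(config=config, records=table, anova=anova, calibrations=calibrations)
    if config.output_dir:
        result.save(config.output_dir)
    logger.info("study done: %d metric records", len(table))
    return result
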