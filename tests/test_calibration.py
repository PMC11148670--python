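"""N-pose, functional and manual-alignment calibration behavior."""

import numpy as np
import pytest

from elbowcal import rotations as rot
from elbowcal.calibration import (
    MANUAL_ALIGNMENT_MATRIX,
    CalibrationError,
    InsufficientMotionError,
    StillnessError,
    calibrate_functional,
    calibrate_manual,
    calibrate_npose,
    estimate_hinge_axis,
    translate_axis,
)
from elbowcal.kinematics import apply_calibration, elbow_angles
from elbowcal.series import InertialRecording
from elbowcal.simulate import (
    NOMINAL_MOUNT,
    SEGMENTS,
    SubjectProfile,
    corrupt_to_imu,
    forward_kinematics,
    generate_subject_trials,
    generate_task_trajectory,
)
from elbowcal.study import calibrate_subject

from conftest import random_quaternions


def hinge_recording(axis, n=500, rate=60.0, noise_sd=0.0, rng=None, amplitude=1.0):
    """Oscillatory single-axis gyro recording about a fixed sensor-frame axis."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    t = np.arange(n) / rate
    speed = amplitude * np.sin(2 * np.pi * 0.5 * t)
    gyro = speed[:, None] * axis
    if noise_sd > 0:
        gyro = gyro + rng.normal(0, noise_sd, (n, 3))
    q = np.tile(rot.quat_identity(), (n, 1))
    return InertialRecording(t, q, gyro, np.zeros((n, 3)))


class TestHingeAxis:
    def test_noise_free_axis_exact(self):
        est = estimate_hinge_axis(hinge_recording([0, 0, 1]))
        assert np.allclose(est.axis, [0, 0, 1], atol=1e-12)
        assert est.residual_ratio == pytest.approx(0.0, abs=1e-12)

    def test_noisy_axis_recovered(self, rng):
        est = estimate_hinge_axis(hinge_recording([0, 0, 1], noise_sd=0.01, rng=rng))
        assert abs(est.axis @ np.array([0, 0, 1.0])) > 0.999

    def test_dominant_axis_wins_energy_split(self, rng):
        # 90%/10% energy split between two orthogonal axes
        t = np.arange(1000) / 60.0
        major = np.sqrt(0.9) * np.sin(2 * np.pi * 0.5 * t)
        minor = np.sqrt(0.1) * np.sin(2 * np.pi * 1.7 * t)
        gyro = major[:, None] * np.array([1.0, 0, 0]) + minor[:, None] * np.array([0, 1.0, 0])
        rec = InertialRecording(t, np.tile(rot.quat_identity(), (1000, 1)), gyro, np.zeros((1000, 3)))
        est = estimate_hinge_axis(rec)
        # brute-force oracle: energy-maximizing axis over a fine grid
        best, best_energy = None, -1.0
        for theta in np.linspace(0, np.pi, 721):
            cand = np.array([np.cos(theta), np.sin(theta), 0.0])
            energy = np.sum((gyro @ cand) ** 2)
            if energy > best_energy:
                best, best_energy = cand, energy
        assert abs(est.axis @ best) > 0.9999

    def test_sign_follows_first_lobe(self):
        est = estimate_hinge_axis(hinge_recording([0, 0, 1]))
        assert est.axis[2] > 0  # first half-cycle rotates positively
        rec = hinge_recording([0, 0, 1])
        rec.gyro *= -1
        est_neg = estimate_hinge_axis(rec)
        assert est_neg.axis[2] < 0

    def test_error_monotone_in_noise(self):
        truth = np.array([0, 0, 1.0])
        errors = []
        for sd in (0.1, 0.05, 0.01, 0.0):
            rng = np.random.default_rng(11)  # same draws, scaled noise
            est = estimate_hinge_axis(hinge_recording(truth, n=1000, noise_sd=sd, rng=rng))
            errors.append(np.degrees(np.arccos(np.clip(abs(est.axis @ truth), -1, 1))))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-6

    def test_insufficient_motion_rejected(self):
        rec = hinge_recording([0, 0, 1], amplitude=0.1)
        with pytest.raises(InsufficientMotionError):
            estimate_hinge_axis(rec)

    def test_short_recording_rejected(self):
        rec = hinge_recording([0, 0, 1], n=60)
        with pytest.raises(InsufficientMotionError):
            estimate_hinge_axis(rec)


class TestTranslateAxis:
    def test_same_frame_is_identity(self):
        q = rot.quat_from_axis_angle([0.3, 0.5, 1], 40.0)
        assert np.allclose(translate_axis([1, 0, 0], q, q), [1, 0, 0], atol=1e-12)

    def test_matches_matrix_oracle(self, rng):
        q_src = random_quaternions(rng, 100)
        q_tgt = random_quaternions(rng, 100)
        for qs, qt in zip(q_src, q_tgt):
            out = translate_axis([1, 0, 0], qs, qt)
            oracle = rot.quat_to_matrix(qt).T @ rot.quat_to_matrix(qs) @ np.array([1.0, 0, 0])
            assert np.allclose(out, oracle, atol=1e-12)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)


class TestManualAlignment:
    def test_matrix_is_signed_permutation(self):
        m = MANUAL_ALIGNMENT_MATRIX
        assert np.linalg.det(m) == pytest.approx(1.0)
        assert np.allclose(np.abs(m).sum(axis=0), 1)
        # segment X = -sensor y, Y = sensor x, Z = sensor z
        assert np.allclose(m[:, 0], [0, -1, 0])
        assert np.allclose(m[:, 1], [1, 0, 0])
        assert np.allclose(m[:, 2], [0, 0, 1])

    def test_quaternion_value(self):
        result = calibrate_manual()
        expected = np.array([np.sqrt(2) / 2, 0.0, 0.0, -np.sqrt(2) / 2])
        assert rot.quat_allclose(result.q0_upper_arm, expected)
        assert rot.quat_allclose(result.q0_lower_arm, expected)

    def test_deterministic_and_input_free(self):
        a, b = calibrate_manual(), calibrate_manual()
        assert np.array_equal(a.q0_upper_arm, b.q0_upper_arm)
        assert a.method == "MA"


class TestNPose:
    def test_yaw_invariance(self, ideal_trials):
        """A global heading rotation of all sensors leaves q0 unchanged."""
        static = ideal_trials["npose_static"].imu_streams
        base = calibrate_npose(static)
        yaw = rot.quat_from_axis_angle([0, 0, 1], 30.0)
        yawed = {
            seg: InertialRecording(
                r.t, rot.quat_multiply(np.tile(yaw, (len(r), 1)), r.q), r.gyro, r.accel
            )
            for seg, r in static.items()
        }
        rotated = calibrate_npose(yawed)
        assert rot.quat_allclose(base.q0_upper_arm, rotated.q0_upper_arm, atol_deg=1e-6)
        assert rot.quat_allclose(base.q0_lower_arm, rotated.q0_lower_arm, atol_deg=1e-6)

    def test_moving_static_recording_rejected(self, ideal_profile):
        angles, trunk = generate_task_trajectory("flexion", 3.0, 2, 60.0, ideal_profile)
        moving = corrupt_to_imu(forward_kinematics(angles, trunk), ideal_profile)
        with pytest.raises(StillnessError):
            calibrate_npose(moving)

    def test_missing_segment_rejected(self, ideal_trials):
        static = dict(ideal_trials["npose_static"].imu_streams)
        static.pop("thorax")
        with pytest.raises(CalibrationError, match="thorax"):
            calibrate_npose(static)

    def test_gravity_diagnostics_present(self, ideal_trials):
        result = calibrate_npose(ideal_trials["npose_static"].imu_streams)
        assert "gravity_tilt_deg_thorax" in result.diagnostics
        assert result.diagnostics["gravity_tilt_deg_thorax"] < 1.0


class TestFunctional:
    def test_recovers_axis_despite_20deg_mounting_error(self):
        mis = {seg: rot.quat_from_axis_angle([1, 1, 0], 20.0) for seg in SEGMENTS}
        profile = SubjectProfile(
            carrying_baseline_deg=12.0,
            carrying_span_deg=0.0,
            mounting_misalignment=mis,
            seed=5,
        )
        trials = generate_subject_trials(profile)
        result = calibrate_functional(
            trials["fe_calibration"].imu_streams["upper_arm"],
            trials["fe_calibration"].imu_streams["lower_arm"],
            trials["ps_calibration"].imu_streams["lower_arm"],
        )
        # ground-truth flexion axis in the upper-arm sensor frame is the
        # lateral column of the true (mount-composed) calibration rotation
        mount = rot.quat_multiply(NOMINAL_MOUNT, mis["upper_arm"])
        true_axis = rot.quat_to_matrix(rot.quat_inverse(mount))[:, 2]
        got_axis = rot.quat_to_matrix(result.q0_upper_arm)[:, 2]
        err = np.degrees(np.arccos(np.clip(got_axis @ true_axis, -1, 1)))
        assert err < 0.1

    def test_axis_error_small_under_gyro_noise(self):
        profile = SubjectProfile(
            carrying_baseline_deg=12.0, carrying_span_deg=0.0, gyro_noise_sd=0.02, seed=9
        )
        trials = generate_subject_trials(profile, duration_s=1000 / 60.0)
        result = calibrate_functional(
            trials["fe_calibration"].imu_streams["upper_arm"],
            trials["fe_calibration"].imu_streams["lower_arm"],
            trials["ps_calibration"].imu_streams["lower_arm"],
        )
        true_axis = rot.quat_to_matrix(rot.quat_inverse(NOMINAL_MOUNT))[:, 2]
        got_axis = rot.quat_to_matrix(result.q0_upper_arm)[:, 2]
        err = np.degrees(np.arccos(np.clip(got_axis @ true_axis, -1, 1)))
        assert err < 2.0

    def test_static_pronation_recording_rejected(self, ideal_trials):
        fe = ideal_trials["fe_calibration"].imu_streams
        static_ps = ideal_trials["npose_static"].imu_streams["lower_arm"]
        with pytest.raises(InsufficientMotionError):
            calibrate_functional(fe["upper_arm"], fe["lower_arm"], static_ps)


class TestClosedLoop:
    """Zero corruption: every method reproduces task angles to < 1e-6 deg."""

    @pytest.mark.parametrize("method", ["NP", "FC", "MA"])
    def test_zero_error(self, ideal_trials, method):
        cal = calibrate_subject(ideal_trials, (method,))[method]
        trial = ideal_trials["flexion"]
        ua = apply_calibration(trial.imu_streams["upper_arm"].orientation, cal.q0_upper_arm)
        la = apply_calibration(trial.imu_streams["lower_arm"].orientation, cal.q0_lower_arm)
        angles = elbow_angles(ua, la)
        for axis in ("flexion", "carrying", "pronation"):
            assert np.abs(angles.axis(axis) - trial.truth_angles.axis(axis)).max() < 1e-6
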