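"""Virtual-subject generator: trajectories, forward kinematics, IMU corruption."""

import numpy as np
import pytest

from elbowcal import rotations as rot
from elbowcal.kinematics import elbow_angles
from elbowcal.series import OrientationSeries
from elbowcal.simulate import (
    ALL_TRIALS,
    SEGMENTS,
    SubjectProfile,
    carrying_angle_of_flexion,
    corrupt_to_imu,
    forward_kinematics,
    generate_study,
    generate_subject_trials,
    generate_task_trajectory,
)


class TestCarryingAngle:
    def test_baseline_at_full_extension(self):
        p = SubjectProfile(carrying_baseline_deg=14, carrying_span_deg=15)
        assert carrying_angle_of_flexion(0.0, p, "linear") == pytest.approx(14.0)
        assert carrying_angle_of_flexion(0.0, p, "sinusoidal") == pytest.approx(14.0)

    def test_full_span_at_130_degrees(self):
        p = SubjectProfile(carrying_baseline_deg=14, carrying_span_deg=15)
        assert carrying_angle_of_flexion(130.0, p, "linear") == pytest.approx(-1.0)
        assert carrying_angle_of_flexion(130.0, p, "sinusoidal") == pytest.approx(-1.0)

    def test_half_sinusoid_midpoint(self):
        p = SubjectProfile(carrying_baseline_deg=10, carrying_span_deg=12)
        assert carrying_angle_of_flexion(65.0, p, "sinusoidal") == pytest.approx(10 - 6.0)

    def test_span_bound_enforced(self):
        with pytest.raises(ValueError, match="span"):
            SubjectProfile(carrying_span_deg=16.0)


class TestTrajectories:
    def test_flexion_task_has_exactly_reps_maxima(self):
        p = SubjectProfile(seed=1)
        angles, _ = generate_task_trajectory("flexion", 15.0, 5, 60.0, p)
        f = angles.flexion_deg
        maxima = np.sum((f[1:-1] > f[:-2]) & (f[1:-1] > f[2:]))
        assert maxima == 5
        assert np.ptp(angles.pronation_deg) < 5.0

    def test_npose_static_is_constant(self):
        angles, trunk = generate_task_trajectory("npose_static", 3.0, 5, 60.0)
        for axis in ("flexion", "carrying", "pronation"):
            assert np.ptp(angles.axis(axis)) == 0.0
        assert np.max(rot.quat_angle_deg(trunk.q, trunk.q[0])) < 1e-9

    def test_fe_calibration_range(self):
        angles, _ = generate_task_trajectory("fe_calibration", 15.0, 5, 60.0)
        assert angles.flexion_deg.min() == pytest.approx(15.0, abs=2.0)
        assert angles.flexion_deg.max() == pytest.approx(50.0, abs=2.0)

    def test_pronation_task_posture(self):
        angles, _ = generate_task_trajectory("pronation", 15.0, 5, 60.0)
        assert np.allclose(angles.flexion_deg, 90.0)
        assert angles.pronation_deg.min() == pytest.approx(-80.0, abs=1.0)
        assert angles.pronation_deg.max() == pytest.approx(80.0, abs=1.0)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="unknown task"):
            generate_task_trajectory("jumping_jacks")


class TestForwardKinematics:
    def test_zero_angles_align_forearm_with_upper_arm(self):
        p = SubjectProfile(carrying_baseline_deg=0, carrying_span_deg=0)
        angles, trunk = generate_task_trajectory("npose_static", 2.0, 1, 60.0, p)
        segs = forward_kinematics(angles, trunk, p)
        assert np.max(rot.quat_angle_deg(segs["lower_arm"].q, segs["upper_arm"].q)) < 1e-9

    def test_roundtrip_through_elbow_angles(self):
        p = SubjectProfile(carrying_baseline_deg=13, carrying_span_deg=11, seed=2)
        for task in ("flexion", "drinking", "box_off_shelf"):
            angles, trunk = generate_task_trajectory(task, 8.0, 2, 60.0, p)
            segs = forward_kinematics(angles, trunk, p)
            back = elbow_angles(segs["upper_arm"], segs["lower_arm"])
            for axis in ("flexion", "carrying", "pronation"):
                assert np.abs(back.axis(axis) - angles.axis(axis)).max() < 1e-9

    def test_trunk_yaw_leaves_joint_angles_unchanged(self):
        p = SubjectProfile(seed=3)
        angles, trunk = generate_task_trajectory("flexion", 5.0, 2, 60.0, p)
        yaw = rot.quat_from_axis_angle([0, 0, 1], 40.0)
        trunk_yawed = OrientationSeries(
            trunk.t, rot.quat_multiply(np.tile(yaw, (len(trunk), 1)), trunk.q)
        )
        a = forward_kinematics(angles, trunk, p)
        b = forward_kinematics(angles, trunk_yawed, p)
        ja = elbow_angles(a["upper_arm"], a["lower_arm"])
        jb = elbow_angles(b["upper_arm"], b["lower_arm"])
        for axis in ("flexion", "carrying", "pronation"):
            assert np.abs(ja.axis(axis) - jb.axis(axis)).max() < 1e-9


class TestCorruptToImu:
    def test_no_corruption_keeps_truth_under_mounting(self, ideal_profile):
        angles, trunk = generate_task_trajectory("flexion", 5.0, 2, 60.0, ideal_profile)
        truth = forward_kinematics(angles, trunk, ideal_profile)
        imu = corrupt_to_imu(truth, ideal_profile)
        from elbowcal.simulate import NOMINAL_MOUNT

        for seg in SEGMENTS:
            expected = rot.quat_multiply(truth[seg].q, NOMINAL_MOUNT)
            assert np.max(rot.quat_angle_deg(imu[seg].q, expected)) < 1e-9

    def test_static_accelerometer_reads_gravity(self):
        p = SubjectProfile(accel_noise_sd=0.2, seed=4)
        angles, trunk = generate_task_trajectory("npose_static", 10.0, 1, 60.0, p)
        truth = forward_kinematics(angles, trunk, p)
        imu = corrupt_to_imu(truth, p)
        rec = imu["thorax"]
        mean_accel = rec.accel.mean(axis=0)
        n = len(rec)
        # direction matches sensor-frame gravity within 3 sigma / sqrt(n)
        expected = rot.quat_rotate_vector(rot.quat_inverse(rec.q[0]), [0, 0, 9.81])
        assert np.linalg.norm(mean_accel - expected) < 3 * 0.2 / np.sqrt(n) * np.sqrt(3)
        assert np.linalg.norm(mean_accel) == pytest.approx(9.81, abs=0.05)

    def test_gyro_matches_constant_rate_rotation(self):
        """Finite-difference gyro of a 1 rad/s spin about z reads (0,0,1)."""
        n, rate = 600, 60.0
        t = np.arange(n) / rate
        ang = np.degrees(t)  # 1 rad/s
        q = rot.quat_from_axis_angle([0, 0, 1], ang)
        truth = {seg: OrientationSeries(t, q) for seg in SEGMENTS}
        p = SubjectProfile(
            mounting_misalignment={seg: rot.quat_identity() for seg in SEGMENTS}
        )
        # bypass the nominal mount by supplying truth already in sensor frame
        from elbowcal import simulate as sim

        rates = sim._body_rates(q, 1.0 / rate)
        assert np.allclose(rates[1:-1], [0, 0, 1.0], atol=1e-9)

    def test_zero_misalignment_zero_noise_reproducible(self, ideal_profile):
        a = generate_subject_trials(ideal_profile, trials=("flexion",))
        b = generate_subject_trials(ideal_profile, trials=("flexion",))
        assert np.array_equal(
            a["flexion"].imu_streams["lower_arm"].q, b["flexion"].imu_streams["lower_arm"].q
        )


class TestStudyGeneration:
    def test_same_seed_bit_identical(self, zero_corruption_ranges):
        a = generate_study(2, seed=5, config=None, duration_s=5.0)
        b = generate_study(2, seed=5, config=None, duration_s=5.0)
        for subj in a:
            for task in a[subj]:
                assert np.array_equal(
                    a[subj][task].imu_streams["lower_arm"].gyro,
                    b[subj][task].imu_streams["lower_arm"].gyro,
                )

    def test_cardinality(self):
        study = generate_study(3, seed=6, duration_s=5.0)
        assert len(study) == 3
        assert all(len(trials) == len(ALL_TRIALS) for trials in study.values())

    def test_trial_internal_consistency(self):
        """truth_angles always equals elbow_angles(truth_orientations)."""
        study = generate_study(2, seed=8, duration_s=5.0)
        for trials in study.values():
            for trial in trials.values():
                back = elbow_angles(
                    trial.truth_orientations["upper_arm"], trial.truth_orientations["lower_arm"]
                )
                for axis in ("flexion", "carrying", "pronation"):
                    assert np.abs(back.axis(axis) - trial.truth_angles.axis(axis)).max() < 1e-9


class TestDegradationOrdering:
    def test_npose_posture_error_hits_np_not_fc(self):
        """Posture error degrades NP while FC is untouched, monotone in magnitude."""
        from elbowcal.kinematics import apply_calibration
        from elbowcal.study import calibrate_subject

        np_err, fc_err = [], []
        for mag in (0.0, 5.0, 10.0):
            posture = {
                seg: rot.quat_from_axis_angle([1, 0.4, 0.2], mag) for seg in ("upper_arm", "lower_arm")
            }
            posture["thorax"] = rot.quat_identity()
            profile = SubjectProfile(
                carrying_baseline_deg=0.0,
                carrying_span_deg=0.0,
                npose_posture_error=posture,
                seed=10,
            )
            trials = generate_subject_trials(profile)
            cals = calibrate_subject(trials, ("NP", "FC"))
            trial = trials["flexion"]
            for method, sink in (("NP", np_err), ("FC", fc_err)):
                cal = cals[method]
                ua = apply_calibration(trial.imu_streams["upper_arm"].orientation, cal.q0_upper_arm)
                la = apply_calibration(trial.imu_streams["lower_arm"].orientation, cal.q0_lower_arm)
                ja = elbow_angles(ua, la)
                sink.append(np.abs(ja.flexion_deg - trial.truth_angles.flexion_deg).max())
        assert np_err[0] < 1e-6
        assert np_err[0] < np_err[1] < np_err[2]
        assert max(fc_err) < 1e-6

    def test_manual_alignment_error_monotone_in_misalignment(self):
        from elbowcal.calibration import calibrate_manual
        from elbowcal.kinematics import apply_calibration

        errors = []
        for mag in (0.0, 5.0, 10.0):
            mis = {seg: rot.quat_from_axis_angle([0.3, 1, 0.5], mag) for seg in SEGMENTS}
            profile = SubjectProfile(
                carrying_baseline_deg=0.0, carrying_span_deg=0.0,
                mounting_misalignment=mis, seed=11,
            )
            trials = generate_subject_trials(profile, trials=("flexion",))
            cal = calibrate_manual()
            trial = trials["flexion"]
            ua = apply_calibration(trial.imu_streams["upper_arm"].orientation, cal.q0_upper_arm)
            la = apply_calibration(trial.imu_streams["lower_arm"].orientation, cal.q0_lower_arm)
            ja = elbow_angles(ua, la)
            errors.append(np.abs(ja.flexion_deg - trial.truth_angles.flexion_deg).max())
        assert errors[0] < 1e-6
        assert errors[0] < errors[1] < errors[2]
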