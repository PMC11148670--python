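# elbowcal

Sensor-to-segment calibration and 3-DOF elbow joint angles from wearable
inertial measurement units (IMUs), with a virtual-subject simulator and
study-level accuracy statistics.

## The problem

An IMU strapped to the upper arm or forearm measures the orientation of its own
case, not of the bone underneath. Before elbow angles can be reported in
anatomically meaningful terms, each sensor needs a *sensor-to-segment
calibration*: the fixed rotation `q0` between the sensor case frame and the
segment's anatomical frame. Once known, the runtime chain is a single
quaternion composition,

```
q_global←segment = q_global←sensor ⊗ q0
```

and the elbow angle triple is the intrinsic Z–X′–Y″ factorization of the
humerus-to-forearm relative rotation (the ISB elbow convention): flexion(+)/
extension(−) about the lateral Z axis, the carrying angle about the floating X
axis, and pronation(+)/supination(−) about the longitudinal Y axis.

The package implements the three calibration families used in clinical
practice and lets you compare them quantitatively:

* **N-Pose (NP)** — stand still, arms alongside the body; both arm segment
  frames are inherited from the trunk sensor and the gravity vector.
* **Functional calibration (FC)** — prescribed single-plane elbow flexion and
  pronation movements; each movement's hinge axis, extracted from the
  gyroscope stream (first right-singular vector of the angular-rate matrix),
  anchors an anatomical axis, completed by a gravity/vertical reference via
  cross-product frame construction.
* **Manual alignment (MA)** — the sensors are mounted so their case axes
  coincide with the anatomy; `q0` reduces to the fixed permutation
  (X, Y, Z)segment = (−y, x, z)sensor.

Accuracy against a reference (optical motion capture in the lab; exact ground
truth in simulation) is scored per movement repetition on three metrics, in
degrees: **ROM error** = (max−min)ref − (max−min)imu, **RMSE** of the two
self-demeaned series, and **offset** = mean(ref) − mean(imu). A three-way
within-subject ANOVA (calibration × joint axis × task) with generalized eta
squared (η²G) and Greenhouse–Geisser correction summarizes the comparison.

Because real optical+IMU recordings are bulky, the package ships a
virtual-subject simulator that generates ground-truth upper-limb kinematics
for the full protocol (static N-pose, two functional calibration movements,
and five tasks: flexion, pronation, drinking, box-off-shelf, circles) and
corrupts them into IMU streams with mounting misalignment, an imperfect
static posture, gyro/accel noise and heading drift — plus a
flexion-dependent carrying angle (linear or half-sinusoid, up to 15° of
excursion), which is what makes the elbow more than a double hinge.

## Worked example

```python
from elbowcal.study import StudyConfig, run_study

res = run_study(StudyConfig(n_subjects=13, seed=1))
print(res.summary())
```

prints (abridged):

```
Synthetic calibration study: 13 subjects, 5 tasks, 3 calibrations, seed 1 (config 52549bc0799f)

Grand means per calibration (deg):
             rom_error_deg  rmse_deg  offset_deg
calibration
FC                   0.655     0.874      -1.689
MA                  -2.629     1.890       1.046
NP                  -4.015     3.123       2.914

Three-way RM-ANOVA — rmse:
                   effect  df_num  df_den        F      p    ges  gg_epsilon  mauchly_p  gg_applied
              calibration  2.0000 24.0000  41.3035 0.0000 0.4161      0.7809     0.1634       False
       ...
```

Reading the table: under the default study conditions (8–16° resting carrying
angle varying up to 15° with flexion, 5–10° mounting misalignment, 3–10°
N-pose posture error, gyro noise 0.02 rad/s), the N-pose calibration has the
largest waveform error (RMSE 3.1°) because it inherits the arm frames from
the trunk and is hit by both posture error and the subject's carrying angle;
functional calibration tracks the flexion waveform best; manual alignment
sits between, limited purely by placement accuracy. The calibration main
effect on RMSE is strong (F(2,24) = 41.3, p < 0.001, η²G = 0.42). Degrees of
freedom are Greenhouse–Geisser-rescaled wherever Mauchly's test rejects
sphericity.

The same pipeline is scriptable from the shell:

```
elbowcal simulate --config study.yaml --out trials/
elbowcal calibrate trials/S01 --out cal/
elbowcal angles trials/S01/flexion --calibration cal/calibration_FC.json --out angles.csv
elbowcal metrics trials/S01/flexion --angles angles.csv --out metrics.csv
elbowcal study --config study.yaml --out results/
elbowcal replicate <dataset-dir> --out results/   # real-data adapter
```

## Layout

| module | contents |
| --- | --- |
| `elbowcal.rotations` | quaternion/matrix algebra, frame-from-axes, ZXY Euler |
| `elbowcal.series` | OrientationSeries, InertialRecording, JointAngleSeries |
| `elbowcal.calibration` | NP / FC / MA calibration, hinge-axis estimation |
| `elbowcal.kinematics` | calibration application, elbow angle computation |
| `elbowcal.metrics` | repetition segmentation, ROM error / RMSE / offset |
| `elbowcal.anova` | within-subject ANOVA, generalized eta squared, GG/Mauchly |
| `elbowcal.simulate` | virtual subjects, trajectories, IMU corruption |
| `elbowcal.study` | StudyConfig / StudyResult, end-to-end runner |
| `elbowcal.io`, `elbowcal.adapters`, `elbowcal.cli` | CSV/JSON formats, dataset adapter, CLI |

See `docs/methods.md` for the model, conventions, parameter defaults and
known limitations.
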