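import numpy as np
import pytest

from elbowcal.simulate import (
    ZERO_CORRUPTION_RANGES,
    SubjectProfile,
    generate_subject_trials,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def ideal_profile():
    """Perfect mounting/posture/sensors and no carrying angle: exact closed loop."""
    return SubjectProfile(
        carrying_baseline_deg=0.0, carrying_span_deg=0.0, carrying_shape="linear", seed=7
    )


@pytest.fixture
def ideal_trials(ideal_profile):
    return generate_subject_trials(ideal_profile)


@pytest.fixture
def zero_corruption_ranges():
    return dict(ZERO_CORRUPTION_RANGES)


def random_quaternions(rng, n):
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q[q[:, 0] < 0] *= -1
    return q
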