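import math

import pytest
from hypothesis import HealthCheck, settings

from ciliabeat.datasets import load_pilot_cohort
from ciliabeat.kinematics import Point2D
from ciliabeat.simulation import BeatModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """The bundled 34-patient reference cohort with derived gold standard."""
    return load_pilot_cohort()


@pytest.fixture()
def beat_model():
    """A mid-field cilium beating at 2.5 Hz through 90 degrees.

    2.5 Hz is exactly 142 frames at 355 frames/s, so phase boundaries fall
    on the frame grid and round trips are frame-exact.
    """
    return BeatModel.from_phase_fractions(
        base=Point2D(128 * 0.13, 96 * 0.13),
        length=5.0,
        angle_amplitude=math.radians(90),
        freq=2.5,
        base_angle=0.3,
        seed=11,
    )
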