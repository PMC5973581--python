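import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orthomove import RigidTransform
from orthomove.simulate import default_template

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


def random_rigid(rng) -> RigidTransform:
    """A random proper rigid transform for gauge/invariance tests."""
    from orthomove.simulate import random_pose

    return random_pose(rng)


@pytest.fixture(scope="session")
def axis_frame():
    """Axis-aligned anatomical frame with the occlusal plane at x = 0."""
    from orthomove import Plane, ReferenceFrame

    frame = ReferenceFrame(
        np.zeros(3),
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
    )
    plane1 = Plane(np.array([1.0, 0.0, 0.0]), 0.0)
    return frame, plane1
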