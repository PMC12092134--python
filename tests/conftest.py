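import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from jumpsim import (
    Actuator,
    Joint,
    Model,
    PathPoint,
    Segment,
    Shape,
    WrapCylinder,
    make_reference_guineafowl,
    make_reference_human,
    make_toy_jumper,
)


@pytest.fixture(scope="session")
def human_model1():
    return make_reference_human("model1", "full_extension")


@pytest.fixture(scope="session")
def guineafowl_model1():
    return make_reference_guineafowl("model1")


@pytest.fixture(scope="session")
def toy_deep():
    return make_toy_jumper("deep_crouch")


@pytest.fixture()
def two_link():
    """Minimal 2-segment hopper: one hinge, one wrapped actuator."""
    s1 = Segment("a", Shape("cylinder", 0.3, radius=0.02), 1000.0)
    s2 = Segment("b", Shape("cylinder", 0.3, radius=0.02), 1000.0)
    joint = Joint("j", "a", "b", anchor=(0.3, 0.0), angle_lo=0.0, angle_hi=95.0)
    act = Actuator(
        "m",
        [PathPoint("a", (0.15, -0.035)), PathPoint("b", (0.15, -0.035))],
        wrap=WrapCylinder("b", (0.0, 0.0), 0.04, side=1, after_point=0),
        fl_mm=50.0,
        pcsa_mm2=100.0,
        actions=[("j", "flexor")],
    )
    return Model(
        taxon="twolink",
        body_mass=s1.mass + s2.mass,
        segments=[s1, s2],
        joints=[joint],
        actuators=[act],
        starting_pose={"j": 45.0},
    )
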