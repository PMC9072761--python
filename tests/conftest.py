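import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from soundscapes.acoustics import AtmosphericConditions, GroundProfile, PropagationGeometry
from soundscapes.fixtures import vehicle_power_laws


@pytest.fixture(scope="session")
def std_conditions():
    return AtmosphericConditions(temperature_c=20.0, relative_humidity=60.0, pressure_bar=1.01325)


@pytest.fixture(scope="session")
def std_ground():
    return GroundProfile(hardness=0.5)


@pytest.fixture(scope="session")
def std_geometry():
    return PropagationGeometry(source_height=0.5, receiver_height=1.5, distance=100.0)


@pytest.fixture(scope="session")
def sedan_laws():
    return vehicle_power_laws("sedan")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
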