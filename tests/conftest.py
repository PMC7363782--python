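import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neoloop.physiology import InfusionInput, PatientParams

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def params():
    """Nominal preterm parameter set."""
    return PatientParams()


@pytest.fixture
def nutrition():
    """Standard parenteral dextrose load."""
    return InfusionInput(maintenance_dextrose=8.4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
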