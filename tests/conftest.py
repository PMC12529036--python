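import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyng import (
    EnvironmentState,
    standard_reference_set,
    standard_target_al,
)

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def env20():
    """Still-lab microclimate: 20 °C, RH 0.40, darkness, gentle fan."""
    return EnvironmentState(time=0.0, T_air=293.15, RH_air=0.40,
                            P_atm=101325.0, wind=0.4, PPFD=0.0)


@pytest.fixture
def reference_set():
    return standard_reference_set()


@pytest.fixture
def al_samples():
    """Five references plus the fixed-conductance target AL."""
    return standard_reference_set() + [standard_target_al(0.31)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
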