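import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dimerfit.presets import EQ_FRET, EQ_KINETICS, KIN_C3  # noqa: E402


@pytest.fixture(scope="session")
def eq_fret():
    """Dilution-analysis constants: K_D = 80 nM, saturated-dimer K_D'' = 5 K_D."""
    return EQ_FRET


@pytest.fixture(scope="session")
def eq_kinetics():
    return EQ_KINETICS


@pytest.fixture(scope="session")
def kin_c3():
    """Kinetic constants of the C3 interface destabilizer."""
    return KIN_C3


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
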