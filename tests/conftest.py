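import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import amdmem as am

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def thermo300():
    return am.ThermoParams(temperature=300.0)


@pytest.fixture(scope="session")
def toy_membrane():
    """Static single-frame pseudo-bilayer with a peptide 28 A above center."""
    return am.gen_toy_membrane_system(
        n_lipids_per_leaflet=9, peptide_z_offset=28.0, seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
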