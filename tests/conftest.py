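import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ohcamp

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gp():
    """Guinea-pig 4 kHz reference parameter set."""
    return ohcamp.guinea_pig_4khz()


@pytest.fixture(scope="session")
def gp_groups(gp):
    return ohcamp.derive_groups(gp)


@pytest.fixture(scope="session")
def fm():
    """Figure-mode dimensionless groups (omega_bar_eta pinned at 10)."""
    return ohcamp.figure_mode_groups()


@pytest.fixture()
def hf_grid():
    return ohcamp.FrequencyGrid.log(0.3, 3.0, 400)


@pytest.fixture()
def single(request):
    def make(wb):
        return ohcamp.FrequencyGrid(np.atleast_1d(np.asarray(wb, dtype=float)))
    return make
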