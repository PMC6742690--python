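import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from t1dsim import NOD, ParameterSet
from t1dsim.simulator import default_initial_state


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def nod_params(params):
    return params.with_preset(NOD)


@pytest.fixture(scope="session")
def nod_init(nod_params):
    return default_initial_state(nod_params, preset=NOD)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
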