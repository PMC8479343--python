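import numpy as np
import pytest

from statswitch import ModelParams, Thresholds, default_initial_state


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def ic(params):
    return default_initial_state(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210594)
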