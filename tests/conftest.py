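import numpy as np
import pytest

from gliawave import ChIParams, GJParams, resting_state


@pytest.fixture(scope="session")
def chi():
    return ChIParams()


@pytest.fixture(scope="session")
def gj():
    return GJParams()


@pytest.fixture(scope="session")
def rest(chi):
    return resting_state(chi)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
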