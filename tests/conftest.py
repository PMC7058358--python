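import numpy as np
import pytest

from crnlyap import fixtures


@pytest.fixture(scope="session")
def ptm_full():
    return fixtures.ptm_full()


@pytest.fixture(scope="session")
def ptm_reduced():
    return fixtures.ptm_reduced()


@pytest.fixture(scope="session")
def proofreading2():
    return fixtures.kinetic_proofreading(2)


@pytest.fixture(scope="session")
def distributive():
    return fixtures.distributive_double()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
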