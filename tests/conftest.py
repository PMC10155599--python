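import numpy as np
import pytest

from surftask.icomesh import build_icosphere


@pytest.fixture(scope="session")
def mesh2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def mesh3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def mesh0():
    return build_icosphere(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
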