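import numpy as np
import pytest

from lrcpg import CenterParams, NetworkConfig, generate_fixtures


@pytest.fixture(scope="session")
def params():
    return CenterParams()


@pytest.fixture(scope="session")
def cfg():
    return NetworkConfig()


@pytest.fixture(scope="session")
def fixtures():
    return generate_fixtures()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150513)
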