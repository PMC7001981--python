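import numpy as np
import pytest

from habitcache import build_model, build_topology


@pytest.fixture(scope="session")
def topology():
    return build_topology()


@pytest.fixture(scope="session")
def model():
    """Generative model with the package's default parameters."""
    return build_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
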