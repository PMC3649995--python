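import numpy as np
import pytest

from tissueqtl.configs import default_weights, enumerate_configs
from tissueqtl.priors import build_grid


@pytest.fixture(scope="session")
def default_grid():
    return build_grid("default")


@pytest.fixture(scope="session")
def configs5():
    return enumerate_configs(5)


@pytest.fixture(scope="session")
def weights5():
    return default_weights(5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_pair(rng, n=100, b=0.0, maf=0.3, sigma=1.0):
    """One tissue's (y, g) with standardized effect b."""
    g = rng.binomial(2, maf, n).astype(float)
    y = b * sigma * g + sigma * rng.standard_normal(n)
    return y, g
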