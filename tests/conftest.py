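import numpy as np
import pytest

import entrospect as E


@pytest.fixture(scope="session")
def logistic_long():
    """10^5 points of the fully chaotic logistic map (x0 = 0.4)."""
    return E.logistic_map(100_000, r=4.0, x0=0.4, transient=1000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_series():
    """A 200-point white-noise series for grid/compatibility tests."""
    return np.random.default_rng(7).normal(0.0, 1.0, 200)


def random_pmf(rng, k):
    """Dirichlet-uniform random PMF with k outcomes."""
    return rng.dirichlet(np.ones(k))
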