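import numpy as np
import pytest

from vsglearn import LIFParams, SpikePattern, make_fixtures, poisson_pattern


@pytest.fixture(scope="session")
def params():
    return LIFParams()


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pattern():
    """50 afferents at a moderate rate; enough structure for most checks."""
    return poisson_pattern(50, 15.0, 200.0, seed=42)


@pytest.fixture(scope="session")
def toy_pattern():
    return SpikePattern(3, 100.0, [np.array([10.0]), np.array([15.0, 40.0]),
                                   np.array([30.0])])
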