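import numpy as np
import pytest

from uvcalib import default_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default noisy synthetic study (16 train + 9 test, sigma=0.002)."""
    return default_scenario(seed=1)


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Same study without noise: exact Beer-Lambert rank-3 mixtures."""
    return default_scenario(seed=1, sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
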