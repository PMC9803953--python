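import numpy as np
import pytest
from hypothesis import settings

from phosid.chem import default_probe
from phosid.synthetic import make_proteome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def probe():
    return default_probe()


@pytest.fixture(scope="session")
def proteome():
    """Small random proteome shared across search tests."""
    return make_proteome(25, seed=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
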