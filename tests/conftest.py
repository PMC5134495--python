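import numpy as np
import pytest
from hypothesis import settings

from lenssr.resample import ResampleConfig, hf_decompose
from lenssr.synthcells import make_library

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rcfg():
    return ResampleConfig()


@pytest.fixture(scope="session")
def small_library():
    """Small HR phantom library (5 per type, 48 px) shared across tests."""
    return make_library(per_type=5, size=48, seed=42)


@pytest.fixture(scope="session")
def small_pairs(small_library, rcfg):
    return [hf_decompose(e.image, rcfg, e.cell_type) for e in small_library]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
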