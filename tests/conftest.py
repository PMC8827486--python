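import numpy as np
import pytest

from lfpwaves.simulate import build_reference_library


@pytest.fixture(scope="session")
def library():
    """Default 72-type reference library (noise-averaged fingerprints)."""
    return build_reference_library(seed=0)


@pytest.fixture(scope="session")
def library_noise_free():
    """Reference library built at sigma = 0 (exact fingerprints)."""
    return build_reference_library(seed=0, sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
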