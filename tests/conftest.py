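import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A reproducible 20-image mixed dataset (10 dense, 10 sparse)."""
    from conefinder import generate_dataset
    return generate_dataset(20, 0.5, seed=7)
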