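import numpy as np
import pytest

from footkin.synthetic import GaitModelParams, generate


@pytest.fixture(scope="session")
def noiseless_rec():
    """Default synthetic recording with zero marker noise (shared, read-only)."""
    return generate(GaitModelParams(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_rec():
    """Default synthetic recording with the standard 2 mm marker noise."""
    return generate(GaitModelParams(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
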