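import numpy as np
import pytest

from ivdquant.phantom import generate_phantom, healthy_spec


@pytest.fixture(scope="session")
def healthy_sample():
    """Noiseless default phantom shared across read-only tests."""
    return generate_phantom(healthy_spec())

@pytest.fixture(scope="session")
def noisy_sample():
    return generate_phantom(healthy_spec(noise_sd=5.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
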