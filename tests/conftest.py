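import numpy as np
import pytest

from neuroseg import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless 32³ phantom with two neurites and one soma."""
    cfg = PhantomConfig(shape=(32, 32, 32), n_neurites=2, noise_sigma=0.0,
                        illumination_gradient=0.0, seed=7)
    image, mask = generate_phantom(cfg)
    return image, mask


@pytest.fixture(scope="session")
def default_phantom():
    """The default noisy 64³ scene the pipeline is exercised on."""
    cfg = PhantomConfig(seed=11)
    image, mask = generate_phantom(cfg)
    return image, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
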