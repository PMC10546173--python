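import numpy as np
import pytest

from mcnn.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_disc_dataset():
    """Small, strongly separable disc/cup set for fast end-to-end tests."""
    config = SyntheticConfig(
        mode="disc_cup", n_per_class=12, image_size=(32, 32),
        effect_size=4.0, noise_sd=0.02, seed=20,
    )
    images, labels, manifest = generate(config)
    return images, labels, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
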