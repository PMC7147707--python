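import numpy as np
import pytest
from hypothesis import settings

import thermofoot as tf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def butterfly():
    """One noiseless control thermogram with its planted arch band."""
    spec = tf.SyntheticSpec(seed=1, noise_sd=0.0)
    return tf.generate_synthetic(spec), tf.arch_band_mask(spec), spec


@pytest.fixture(scope="session")
def rect_mask():
    mask = np.zeros((100, 40), dtype=bool)
    mask[:, :] = True
    return mask
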