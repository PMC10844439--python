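import numpy as np
import pytest

from sdnet.backbones import ProbabilityMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_probability_map(rng, shape):
    """A valid two-class posterior grid with the given spatial shape."""
    fg = rng.uniform(0.0, 1.0, size=shape)
    return ProbabilityMap(np.stack([1.0 - fg, fg]))


def random_binary_mask(rng, shape):
    return (rng.uniform(size=shape) > 0.5).astype(np.uint8)


@pytest.fixture
def prob_map_factory(rng):
    return lambda shape=(4, 4, 4): random_probability_map(rng, shape)


@pytest.fixture
def mask_factory(rng):
    return lambda shape=(4, 4, 4): random_binary_mask(rng, shape)
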