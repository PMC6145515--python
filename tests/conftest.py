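import numpy as np
import pytest

from weberelastica import ImageField, default_shapes_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_field(rng):
    """Small random strictly-positive field, spacing 1 (stencil oracles)."""
    return ImageField(rng.uniform(10.0, 200.0, size=(6, 6)), spacing=1.0)


@pytest.fixture
def phantom64():
    return default_shapes_phantom(64, spacing=1.0)


def random_positive_field(rng, shape=(6, 6), spacing=1.0, lo=10.0, hi=200.0):
    return ImageField(rng.uniform(lo, hi, size=shape), spacing=spacing)
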