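import numpy as np
import pytest

from sinusflow import FluidProperties, default_tree


@pytest.fixture
def blood() -> FluidProperties:
    return FluidProperties()


@pytest.fixture
def average_tree():
    return default_tree()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
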