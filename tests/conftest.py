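import numpy as np
import pytest

from agrigame import BASELINE_PARAMETERS, MixedState


@pytest.fixture
def baseline():
    """The benchmark parameter set shared by all scenario presets."""
    return BASELINE_PARAMETERS


@pytest.fixture
def baseline_state():
    return MixedState(0.4, 0.2, 0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)


def random_state(rng: np.random.Generator) -> MixedState:
    x, y, z = rng.uniform(0.0, 1.0, size=3)
    return MixedState(float(x), float(y), float(z))
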