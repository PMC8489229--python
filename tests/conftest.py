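import numpy as np
import pytest

import diffem as de


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_map(rng):
    return de.MapGrid(rng.standard_normal((16, 16, 16)), [16.0, 16.0, 16.0])


@pytest.fixture
def toy_model():
    return de.make_toy_model(5, box=16.0, seed=42)


@pytest.fixture
def carbon_model():
    """Six carbons in a 16 A box, used by the omit-map fixtures."""
    return de.make_toy_model(6, box=16.0, seed=11, elements=("C",))
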