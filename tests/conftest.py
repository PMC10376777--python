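import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid_8x8(rng):
    """Small token grid (1, 8, 8, 6) used by several attention tests."""
    return rng.standard_normal((1, 8, 8, 6)).astype(np.float32)
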