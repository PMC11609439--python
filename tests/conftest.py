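import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_maps(rng):
    """100 random small feature maps for oracle-equivalence sweeps."""
    return [rng.standard_normal((2, 4, 3, 3)) for _ in range(100)]
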