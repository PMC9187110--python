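import numpy as np
import pytest

from rankforage import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paper_cfg():
    """The published default condition (full scale)."""
    return SimConfig()


@pytest.fixture
def tiny_cfg():
    """A fast desk-scale condition for engine tests."""
    return SimConfig(
        grid_side=10,
        updates=100,
        sample_interval=10,
        window=50,
        replicates=2,
        seed=7,
    )
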