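import numpy as np
import pytest

from pronephros import ZStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack(rng):
    """Factory for small random two-channel stacks."""

    def make(n_slices=10, h=24, w=24, pixel_size=1.0, z_interval=2.0, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        vox = r.uniform(0.0, 100.0, size=(2, n_slices, h, w))
        return ZStack(vox, ("GFP", "dye"), pixel_size, z_interval)

    return make
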