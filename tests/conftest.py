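import numpy as np
import pytest

from blinkcount import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack_factory():
    """Seeded random uint stacks of a requested shape."""

    def make(seed, shape=(6, 8, 8), dtype=np.uint8):
        gen = np.random.default_rng(seed)
        info = np.iinfo(dtype)
        data = gen.integers(info.min, info.max + 1, size=shape, dtype=dtype)
        return ImageStack(data)

    return make


@pytest.fixture
def single_transient_stack():
    """One isolated pixel carrying the trace (0, 10, 0, 0, ...) on a zero field."""
    data = np.zeros((6, 9, 9), dtype=np.uint8)
    data[1, 4, 4] = 10
    return ImageStack(data)


@pytest.fixture
def block_transient_stack():
    """A 3x3 block of pixels all flashing (0, 10, 0) — survives the median."""
    data = np.zeros((6, 9, 9), dtype=np.uint8)
    data[1, 3:6, 3:6] = 10
    return ImageStack(data)
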