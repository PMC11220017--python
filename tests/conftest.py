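import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracle` importable

from ewsfd import FrameStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_stack(rng):
    """Seeded uniform-random 16-bit stack, 5 frames of 16x16."""
    return FrameStack(
        rng.integers(0, 1 << 16, size=(5, 16, 16)), container_bits=16
    )
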