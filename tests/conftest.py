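import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose _oracles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ring_mask():
    """3x3 block with a false center: one component, one hole."""
    m = np.ones((3, 3), dtype=bool)
    m[1, 1] = False
    return m
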