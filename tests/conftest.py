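import sys
from pathlib import Path

import numpy as np
import pytest

# make the sibling oracle helpers importable as `oracles`
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """A 16x16 8-bit patch with rich texture."""
    return rng.integers(0, 256, size=(16, 16))
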