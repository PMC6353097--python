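import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from nsalign.structures import make_permuted_pair, make_synthetic_chain


@pytest.fixture(scope="session")
def helix20():
    return make_synthetic_chain("helix", 20, 0)


@pytest.fixture(scope="session")
def walk30():
    return make_synthetic_chain("walk", 30, 7)


@pytest.fixture(scope="session")
def walk60():
    return make_synthetic_chain("walk", 60, 11)


@pytest.fixture(scope="session")
def circular_pair(walk60):
    """Noise-free circularly permuted copy of walk60 with its ground truth."""
    other, truth = make_permuted_pair(
        walk60, [(30, 60, "forward"), (0, 30, "forward")], noise_sigma=0.0, seed=1
    )
    return walk60, other, truth


@pytest.fixture(scope="session")
def reversed_pair(walk60):
    """Copy of walk60 with its second half reversed, plus ground truth."""
    other, truth = make_permuted_pair(
        walk60, [(0, 30, "forward"), (30, 60, "reverse")], noise_sigma=0.0, seed=2
    )
    return walk60, other, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
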