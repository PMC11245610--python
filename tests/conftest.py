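import numpy as np
import pytest

from phyloclone.trees import ClonalTree


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def chain_tree():
    """F -> 1 -> 2 with proportions (0.5, 0.3, 0.2) and counts (2, 5, 3)."""
    return ClonalTree("chain", [-1, 0, 1], [0.5, 0.3, 0.2], [2, 5, 3])


@pytest.fixture()
def branching_tree():
    """F with children 1 and 2."""
    return ClonalTree("branch", [-1, 0, 0], [0.4, 0.35, 0.25], [4, 3, 3])
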