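import numpy as np
import pytest

from stpotts.graph import NeighborGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_graph_3():
    """Three cells on a line at x = 0, 1, 3 with k = 1."""
    return NeighborGraph(np.array([[1], [0], [1]]), k=1, n=3)


@pytest.fixture
def line_graph_5():
    """Five cells in a k=1 chain: 0<->1, 2->1, 3->2, 4->3."""
    return NeighborGraph(np.array([[1], [0], [1], [2], [3]]), k=1, n=5)
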