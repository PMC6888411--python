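import numpy as np
import pytest

from stprev.basis import build_basis
from stprev.graph import RegionGraph, study7_graph
from stprev.simulate import STUDY_WAVES


@pytest.fixture(scope="session")
def study7():
    return study7_graph()


@pytest.fixture(scope="session")
def waves():
    return STUDY_WAVES


@pytest.fixture(scope="session")
def basis9(waves):
    """Study basis: 9 waves, one interior knot at the centre year."""
    return build_basis(waves, (0.0,))


@pytest.fixture
def cycle4():
    W = np.zeros((4, 4), dtype=int)
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        W[i, j] = W[j, i] = 1
    return RegionGraph(("a", "b", "c", "d"), W)


@pytest.fixture
def path3():
    W = np.zeros((3, 3), dtype=int)
    W[0, 1] = W[1, 0] = 1
    W[1, 2] = W[2, 1] = 1
    return RegionGraph(("a", "b", "c"), W)


def random_connected_graph(rng: np.random.Generator, n: int) -> RegionGraph:
    """Random connected graph: spanning tree plus random extra edges."""
    W = np.zeros((n, n), dtype=int)
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[rng.integers(0, i)]
        W[order[i], j] = W[j, order[i]] = 1
    extra = rng.integers(0, n)
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            W[i, j] = W[j, i] = 1
    return RegionGraph(tuple(f"r{i}" for i in range(n)), W)
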