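import numpy as np
import pytest

from heatrewire import WeightedGraph


@pytest.fixture
def two_node() -> WeightedGraph:
    """Two nodes joined by a single edge of weight 3."""
    return WeightedGraph(np.array([[0.0, 3.0], [3.0, 0.0]]))


@pytest.fixture
def triangle() -> WeightedGraph:
    """Unit-weight triangle (every node has strength 2)."""
    A = np.ones((3, 3)) - np.eye(3)
    return WeightedGraph(A)


@pytest.fixture
def path4() -> WeightedGraph:
    """Unit-weight path 0-1-2-3."""
    A = np.zeros((4, 4))
    for i in range(3):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return WeightedGraph(A)


@pytest.fixture
def two_triangles() -> WeightedGraph:
    """Two disconnected unit-weight triangles on nodes {0,1,2} and {3,4,5}."""
    A = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1.0
    return WeightedGraph(A)


def random_weighted_graph(n: int, density: float, seed: int) -> WeightedGraph:
    """Small random weighted graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    iu, iv = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < density
    w = rng.uniform(0.1, 2.0, size=mask.sum())
    A[iu[mask], iv[mask]] = w
    A[iv[mask], iu[mask]] = w
    return WeightedGraph(A)
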