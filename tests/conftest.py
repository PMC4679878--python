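import numpy as np
import pytest

from cflow.graph_core import WeightedGraph


def random_graph(rng: np.random.Generator, n: int, p: float = 0.5,
                 weighted: bool = True) -> WeightedGraph:
    """Erdos-Renyi style random weighted graph for fixtures."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0) if weighted else 1.0
    return WeightedGraph(w)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def triangle():
    return WeightedGraph(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float))


@pytest.fixture()
def double_star():
    """Two hubs (0, 1) joined by a bridge, four leaves on each hub.

    Every leaf walk deterministically climbs leaf-edge -> bridge and stops:
    leaf edges tie within a hub (excluded by the strict-increase rule) and
    the bridge carries the most shortest paths.
    """
    n = 10
    w = np.zeros((n, n))
    w[0, 1] = w[1, 0] = 1.0
    for leaf in (2, 3, 4, 5):
        w[0, leaf] = w[leaf, 0] = 1.0
    for leaf in (6, 7, 8, 9):
        w[1, leaf] = w[leaf, 1] = 1.0
    return WeightedGraph(w)
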