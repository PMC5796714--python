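import numpy as np
import pytest

from agony import DirectedGraph


def random_graph(rng: np.random.Generator, n_min=2, n_max=6) -> DirectedGraph:
    """A small random directed graph (possibly disconnected, no self-loops)."""
    n = int(rng.integers(n_min, n_max + 1))
    p = rng.uniform(0.1, 0.8)
    edges = [(int(u), int(v)) for u in range(n) for v in range(n)
             if u != v and rng.random() < p]
    return DirectedGraph(edges, nodes=range(n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle():
    """Directed 3-cycle."""
    return DirectedGraph([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def small_dag():
    return DirectedGraph([("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")])
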