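import numpy as np
import pytest

from burstnet.graph import DirectedGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ring_graph(n: int) -> DirectedGraph:
    """Directed ring 0 -> 1 -> ... -> n-1 -> 0."""
    adj = np.zeros((n, n), dtype=bool)
    adj[np.arange(n), (np.arange(n) + 1) % n] = True
    return DirectedGraph(adj)


def complete_graph(n: int) -> DirectedGraph:
    """Complete bidirectional graph without self-loops."""
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    return DirectedGraph(adj)


def random_graph(n: int, p: float, seed: int) -> DirectedGraph:
    rng = np.random.default_rng(seed)
    adj = rng.random((n, n)) < p
    np.fill_diagonal(adj, False)
    return DirectedGraph(adj)
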