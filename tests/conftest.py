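import numpy as np
import pytest

from esa.graph_core import Graph, canonicalize_undirected


def random_graph(rng, n_min=2, n_max=8, p=0.4, d_n=3, d_e=2,
                 bidirectional=True):
    """Seeded random attributed graph (ER topology, gaussian features)."""
    n = int(rng.integers(n_min, n_max + 1))
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    und = np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64)
    g = Graph(node_features=rng.normal(size=(n, d_n)),
              edge_index=und,
              edge_features=rng.normal(size=(und.shape[0], d_e)))
    return canonicalize_undirected(g) if bidirectional else g


def brute_force_edge_mask(edge_index):
    """O(N_e^2) loop oracle for the shared-endpoint predicate."""
    ne = len(edge_index)
    m = np.zeros((ne, ne), dtype=bool)
    for a in range(ne):
        for b in range(ne):
            sa, ta = edge_index[a]
            sb, tb = edge_index[b]
            m[a, b] = (sa == sb) or (ta == tb) or (sa == tb) or (ta == sb)
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def p3():
    """Path graph 0-1-2 with both directions stored."""
    return canonicalize_undirected(Graph(
        node_features=np.eye(3),
        edge_index=np.array([[0, 1], [1, 2]]),
        edge_features=np.array([[1.0], [2.0]])))
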