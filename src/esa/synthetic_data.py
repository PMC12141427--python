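"""Seeded generators for test and training surfaces.

Provides Erdős–Rényi random graphs, graph-level counting targets,
BFS-distance node classification ("infected" source-marking), and a fixed
pair of non-isomorphic graphs that plain 1-WL color refinement cannot
separate but whose line graphs it can.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, shortest_path

from .graph_core import Graph, canonicalize_undirected

__all__ = [
    "SynthSpec",
    "gen_er_graphs",
    "gen_shortest_path_task",
    "gen_counting_task",
    "fixture_wl_pair",
    "color_refinement",
    "triangle_count",
]


@dataclass
class SynthSpec:
    """Parameters for a generator run; the seed fully determines the output."""

    n_graphs: int = 10
    n_min: int = 4
    n_max: int = 10
    p_edge: float = 0.3
    degree_onehot: bool = False
    max_degree: int = 16
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("invalid node-count range")
        if not (0.0 <= self.p_edge <= 1.0):
            raise ValueError("p_edge must be in [0, 1]")


def _er_edge_list(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Single-direction (i < j) edge list of one G(n, p) draw."""
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    return np.stack([iu[keep], ju[keep]], axis=1).astype(np.int64)


def _node_features(n: int, edge_index_undirected: np.ndarray,
                   spec: SynthSpec) -> np.ndarray:
    feats = [np.ones((n, 1))]
    if spec.degree_onehot:
        deg = np.zeros(n, dtype=np.int64)
        for i, j in edge_index_undirected:
            deg[i] += 1
            deg[j] += 1
        onehot = np.zeros((n, spec.max_degree + 1))
        onehot[np.arange(n), np.minimum(deg, spec.max_degree)] = 1.0
        feats.append(onehot)
    return np.concatenate(feats, axis=1)


def gen_er_graphs(spec: SynthSpec) -> List[Graph]:
    """Erdős–Rényi graphs, canonicalized to bidirectional edge storage."""
    if not (0.0 < spec.p_edge <= 1.0):
        raise ValueError("p_edge must be in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_graphs):
        n = int(rng.integers(spec.n_min, spec.n_max + 1))
        und = _er_edge_list(n, spec.p_edge, rng)
        g = Graph(node_features=_node_features(n, und, spec), edge_index=und)
        out.append(canonicalize_undirected(g))
    return out


def _undirected_adjacency(g: Graph) -> np.ndarray:
    a = np.zeros((g.num_nodes, g.num_nodes))
    for i, j in g.edge_index:
        a[i, j] = 1.0
        a[j, i] = 1.0
    np.fill_diagonal(a, 0.0)
    return a


def triangle_count(g: Graph) -> int:
    """Exact triangle count of the underlying undirected simple graph."""
    a = _undirected_adjacency(g)
    return int(round(np.trace(a @ a @ a) / 6.0))


def gen_counting_task(spec: SynthSpec,
                      target: Literal["edge_count", "triangle_count"]
                      = "triangle_count") -> List[Graph]:
    """ER graphs with an exact graph-level counting target."""
    graphs = gen_er_graphs(spec)
    for g in graphs:
        if target == "edge_count":
            y = g.num_edges // 2
        elif target == "triangle_count":
            y = triangle_count(g)
        else:
            raise ValueError(f"unknown counting target {target!r}")
        g.y = np.array([float(y)])
    return graphs


def bfs_distances(g: Graph, source: int) -> np.ndarray:
    """Hop distances from `source`; unreachable nodes get -1."""
    n = g.num_nodes
    a = csr_matrix(_undirected_adjacency(g))
    dist = shortest_path(a, method="BF", unweighted=True, indices=source)
    dist = np.where(np.isinf(dist), -1, dist).astype(np.int64)
    return dist


def gen_shortest_path_task(spec: SynthSpec) -> List[Graph]:
    """BFS-distance node classification on ER graphs.

    One random source node per graph is marked with a one-hot feature
    column; the node label is its hop distance to the source, clipped to
    ``n_classes - 1``, with unreachable nodes assigned the top class.
    """
    if spec.n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_graphs):
        n = int(rng.integers(spec.n_min, spec.n_max + 1))
        und = _er_edge_list(n, spec.p_edge, rng)
        source = int(rng.integers(0, n))
        marker = np.zeros((n, 1))
        marker[source, 0] = 1.0
        feats = np.concatenate([np.ones((n, 1)), marker], axis=1)
        g = canonicalize_undirected(Graph(node_features=feats, edge_index=und))
        dist = bfs_distances(g, source)
        labels = np.where(dist < 0, spec.n_classes - 1,
                          np.minimum(dist, spec.n_classes - 1))
        g.y = labels.astype(np.float64).reshape(-1, 1)
        out.append(g)
    return out


def fixture_wl_pair() -> Tuple[Graph, Graph]:
    """Two fused 6-rings vs. two 5-rings joined by a bridge.

    Both graphs have 10 nodes, 11 undirected edges, identical degree
    sequences, and identical stable 1-WL color histograms — yet they are
    not isomorphic.  Their line graphs are likewise non-isomorphic (the
    line-graph transformation preserves non-isomorphism away from the
    K3/K1,3 exception), although plain color refinement on the line
    graphs still produces identical histograms for this pair.
    """
    # two six-cycles sharing the edge (4, 5)
    ring_a = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)]
    ring_b = [(4, 6), (6, 7), (7, 8), (8, 9), (9, 5)]
    decalin_edges = np.array(ring_a + ring_b, dtype=np.int64)
    # two five-cycles joined by the bridge (4, 5)
    ring_1 = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]
    ring_2 = [(5, 6), (6, 7), (7, 8), (8, 9), (9, 5)]
    bridge = [(4, 5)]
    bicyclo_edges = np.array(ring_1 + ring_2 + bridge, dtype=np.int64)
    feats = np.ones((10, 1))
    g1 = canonicalize_undirected(Graph(node_features=feats.copy(),
                                       edge_index=decalin_edges))
    g2 = canonicalize_undirected(Graph(node_features=feats.copy(),
                                       edge_index=bicyclo_edges))
    return g1, g2


def color_refinement(g: Graph, max_rounds: int = 100) -> Tuple[int, ...]:
    """1-WL color refinement; returns the sorted color-count multiset.

    Nodes start with one shared color; each round a node's new color is the
    hash of (own color, sorted multiset of neighbor colors), relabeled to
    small integers.  Stops when the partition stabilizes.
    """
    n = g.num_nodes
    neighbors: List[set] = [set() for _ in range(n)]
    for i, j in g.edge_index:
        if i != j:
            neighbors[i].add(int(j))
            neighbors[j].add(int(i))
    colors = [0] * n
    for _ in range(max_rounds):
        signatures = [
            (colors[v], tuple(sorted(colors[u] for u in neighbors[v])))
            for v in range(n)
        ]
        relabel = {sig: c for c, sig in enumerate(sorted(set(signatures)))}
        new_colors = [relabel[sig] for sig in signatures]
        if len(set(new_colors)) == len(set(colors)):
            colors = new_colors
            break
        colors = new_colors
    counts = np.bincount(np.asarray(colors))
    return tuple(sorted(int(c) for c in counts if c > 0))


def line_graph_of(g: Graph) -> Graph:
    """Line graph of the underlying undirected simple graph.

    Stored directed duplicates are first reduced to unique unordered
    pairs; those pairs become nodes, adjacent when they share an endpoint.
    """
    pairs = sorted({(min(i, j), max(i, j)) for i, j in g.edge_index})
    und = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    ne = und.shape[0]
    src = und[:, 0][:, None]
    tgt = und[:, 1][:, None]
    adj = (src == src.T) | (tgt == tgt.T) | (src == tgt.T) | (tgt == src.T)
    np.fill_diagonal(adj, False)
    ii, jj = np.nonzero(np.triu(adj))
    edges = np.stack([ii, jj], axis=1).astype(np.int64)
    lg = Graph(node_features=np.ones((max(ne, 1), 1)), edge_index=edges)
    return canonicalize_undirected(lg)
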