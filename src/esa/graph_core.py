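"""Attributed graphs, edge-token construction, batching, and 3D featurization.

Graphs are stored with explicit directed edges: an undirected input is
canonicalized to contain both (i, j) and (j, i), one token per direction.
Edge order is significant and preserved everywhere, since attention masks
are built in token order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Graph",
    "EdgeTokenSet",
    "TokenBatch",
    "InvalidGraphError",
    "BatchIncompatibilityError",
    "build_edge_tokens",
    "canonicalize_undirected",
    "batch_graphs",
    "unbatch",
    "radius_graph",
    "gaussian_basis_expansion",
    "save_jsonl",
    "load_jsonl",
]


class InvalidGraphError(ValueError):
    """Raised when a graph violates its structural invariants."""


class BatchIncompatibilityError(ValueError):
    """Raised when graphs in a batch have mismatched feature widths."""


@dataclass
class Graph:
    """One attributed graph.

    Parameters
    ----------
    node_features : (N_n, d_n) array
    edge_index : (N_e, 2) int array of directed (source, target) pairs
    edge_features : (N_e, d_e) array; ``d_e = 0`` is allowed
    coords : optional (N_n, 3) array of positions in Angstrom
    y : graph-level target vector or node-level target matrix (N_n rows)
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: Optional[np.ndarray] = None
    coords: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None

    def __post_init__(self):
        self.node_features = np.atleast_2d(np.asarray(self.node_features, dtype=np.float64))
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        if self.edge_features is None:
            self.edge_features = np.zeros((self.num_edges, 0))
        self.edge_features = np.asarray(self.edge_features, dtype=np.float64)
        if self.edge_features.ndim == 1:
            self.edge_features = self.edge_features.reshape(self.num_edges, -1)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.num_nodes < 1:
            raise InvalidGraphError("graph must have at least one node")
        if self.num_edges:
            lo, hi = self.edge_index.min(), self.edge_index.max()
            if lo < 0 or hi >= self.num_nodes:
                raise InvalidGraphError(
                    f"edge endpoint out of range [0, {self.num_nodes})")
        if self.edge_features.shape[0] != self.num_edges:
            raise InvalidGraphError(
                f"edge_features has {self.edge_features.shape[0]} rows, "
                f"expected {self.num_edges}")
        if self.coords is not None and self.coords.shape[0] != self.num_nodes:
            raise InvalidGraphError("coords row count must equal node count")

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[0]

    @property
    def node_dim(self) -> int:
        return self.node_features.shape[1]

    @property
    def edge_dim(self) -> int:
        return self.edge_features.shape[1]


@dataclass
class EdgeTokenSet:
    """Edge tokens of a graph: row i is src_feat || tgt_feat || edge_feat."""

    tokens: np.ndarray
    origin: Graph

    @property
    def num_tokens(self) -> int:
        return self.tokens.shape[0]


@dataclass
class TokenBatch:
    """Padded token tensor for a batch of graphs.

    ``pad[b, l]`` is True for real tokens (left-aligned); padded rows are
    zero.  ``graph_map`` maps each real token (in concatenation order) to
    its source graph, ``node_map`` does the same for nodes.
    """

    tokens: np.ndarray            # (B, L, d)
    pad: np.ndarray               # (B, L) bool
    graph_map: np.ndarray         # (total real tokens,)
    node_map: np.ndarray          # (total nodes,)
    edge_index_cat: np.ndarray    # (total edges, 2), node ids offset per graph
    counts: np.ndarray            # (B,) real-token counts

    @property
    def batch_size(self) -> int:
        return self.tokens.shape[0]

    @property
    def max_len(self) -> int:
        return self.tokens.shape[1]


def build_edge_tokens(g: Graph) -> EdgeTokenSet:
    """Concatenate source-node, target-node and edge features per edge."""
    width = 2 * g.node_dim + g.edge_dim
    if g.num_edges == 0:
        return EdgeTokenSet(tokens=np.zeros((0, width)), origin=g)
    src = g.node_features[g.edge_index[:, 0]]
    tgt = g.node_features[g.edge_index[:, 1]]
    tokens = np.concatenate([src, tgt, g.edge_features], axis=1)
    return EdgeTokenSet(tokens=tokens, origin=g)


def canonicalize_undirected(g: Graph) -> Graph:
    """Expand single-direction storage to both directed edges per pair.

    Output order is deterministic: all original edges, then all reversals.
    Edge features are duplicated onto the reversed direction.
    """
    if g.num_edges == 0:
        return Graph(node_features=g.node_features.copy(),
                     edge_index=np.zeros((0, 2), dtype=np.int64),
                     edge_features=g.edge_features.copy(),
                     coords=None if g.coords is None else g.coords.copy(),
                     y=None if g.y is None else g.y.copy())
    pairs = {tuple(e) for e in g.edge_index}
    if len(pairs) != g.num_edges:
        raise InvalidGraphError("duplicate directed edge in input")
    for i, j in g.edge_index:
        if (j, i) in pairs and i != j:
            raise InvalidGraphError(
                f"both directions of ({i}, {j}) already stored; "
                "canonicalize_undirected expects one direction per pair")
    edge_index = np.concatenate([g.edge_index, g.edge_index[:, ::-1]], axis=0)
    edge_features = np.concatenate([g.edge_features, g.edge_features], axis=0)
    return Graph(node_features=g.node_features.copy(), edge_index=edge_index,
                 edge_features=edge_features,
                 coords=None if g.coords is None else g.coords.copy(),
                 y=None if g.y is None else g.y.copy())


def _tokenize(g: Graph, mode: str) -> np.ndarray:
    if mode == "edge":
        return build_edge_tokens(g).tokens
    if mode == "node":
        return g.node_features
    raise ValueError(f"unknown tokenizer {mode!r}")


def batch_graphs(gs: Sequence[Graph],
                 tokenizer: Literal["edge", "node"] = "edge") -> TokenBatch:
    """Pad per-graph token matrices into a (B, L, d) tensor.

    L is the maximum token count in the batch; padding rows are zero and
    flagged False in ``pad``.
    """
    if not gs:
        raise BatchIncompatibilityError("cannot batch an empty graph list")
    dn = gs[0].node_dim
    # edgeless graphs carry no edge-feature width information: ignore them
    de_vals = {g.edge_dim for g in gs if g.num_edges}
    if len(de_vals) > 1:
        raise BatchIncompatibilityError(
            f"edge feature width mismatch across batch: {sorted(de_vals)}")
    # edgeless graphs still declare a width; honor it when unambiguous
    de = (de_vals.pop() if de_vals
          else max((g.edge_dim for g in gs), default=0))
    for g in gs:
        if g.node_dim != dn:
            raise BatchIncompatibilityError(
                f"node feature width mismatch: {g.node_dim} vs {dn}")
    mats = [_tokenize(g, tokenizer) for g in gs]
    counts = np.array([m.shape[0] for m in mats], dtype=np.int64)
    B = len(gs)
    L = int(counts.max()) if B else 0
    d = (2 * dn + de) if tokenizer == "edge" else dn
    tokens = np.zeros((B, L, d))
    pad = np.zeros((B, L), dtype=bool)
    for b, m in enumerate(mats):
        if m.shape[0]:
            tokens[b, : m.shape[0]] = m
            pad[b, : m.shape[0]] = True
    graph_map = np.repeat(np.arange(B), counts)
    node_counts = np.array([g.num_nodes for g in gs], dtype=np.int64)
    node_map = np.repeat(np.arange(B), node_counts)
    offsets = np.concatenate([[0], np.cumsum(node_counts)[:-1]])
    eix = [g.edge_index + offsets[b] for b, g in enumerate(gs) if g.num_edges]
    edge_index_cat = (np.concatenate(eix, axis=0) if eix
                      else np.zeros((0, 2), dtype=np.int64))
    return TokenBatch(tokens=tokens, pad=pad, graph_map=graph_map,
                      node_map=node_map, edge_index_cat=edge_index_cat,
                      counts=counts)


def unbatch(batch: TokenBatch) -> List[np.ndarray]:
    """Recover the per-graph token matrices from a TokenBatch."""
    return [batch.tokens[b, : batch.counts[b]].copy()
            for b in range(batch.batch_size)]


def radius_graph(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Directed edge list connecting all pairs within `cutoff` Angstrom.

    Both directions are emitted, no self-loops, lexicographic (i, j) order.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    n = coords.shape[0]
    within = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    src, tgt = np.nonzero(within)   # nonzero is row-major => lexicographic
    return np.stack([src, tgt], axis=1).astype(np.int64)


def gaussian_basis_expansion(dist: float | np.ndarray,
                             centers: np.ndarray,
                             width: float) -> np.ndarray:
    """Expand distances onto Gaussian basis functions.

    Component c is ``exp(-(dist - centers[c])**2 / (2 * width**2))``.
    A scalar distance yields a vector of ``len(centers)``; an array of
    distances yields one row per distance.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    centers = np.asarray(centers, dtype=np.float64)
    if centers.size == 0:
        raise ValueError("centers must be nonempty")
    d = np.asarray(dist, dtype=np.float64)
    out = np.exp(-((d[..., None] - centers) ** 2) / (2.0 * width ** 2))
    return out


def default_gaussian_centers(cutoff: float, n_centers: int = 128):
    """Evenly spaced centers on [0, cutoff]; width equals the spacing."""
    centers = np.linspace(0.0, cutoff, n_centers)
    width = centers[1] - centers[0] if n_centers > 1 else cutoff
    return centers, width


# -- JSON-lines serialization (fixtures / CLI) ------------------------------

def _graph_to_dict(g: Graph) -> dict:
    d = {
        "node_features": g.node_features.tolist(),
        "edge_index": g.edge_index.tolist(),
        "edge_features": g.edge_features.tolist(),
    }
    if g.coords is not None:
        d["coords"] = g.coords.tolist()
    if g.y is not None:
        d["y"] = g.y.tolist()
    return d


def _graph_from_dict(d: dict) -> Graph:
    ne = len(d["edge_index"])
    ef = d.get("edge_features")
    if ef is not None:
        ef = (np.asarray(ef, dtype=np.float64).reshape(ne, -1)
              if ne else np.zeros((0, 0)))
    return Graph(
        node_features=np.asarray(d["node_features"], dtype=np.float64),
        edge_index=np.asarray(d["edge_index"], dtype=np.int64).reshape(-1, 2),
        edge_features=ef,
        coords=None if d.get("coords") is None else np.asarray(d["coords"]),
        y=None if d.get("y") is None else np.asarray(d["y"], dtype=np.float64),
    )


def save_jsonl(graphs: Sequence[Graph], path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(json.dumps(_graph_to_dict(g)) + "\n")


def load_jsonl(path) -> List[Graph]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(_graph_from_dict(json.loads(line)))
    return out
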