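"""Edge- and node-adjacency attention masks, single-graph and batched.

Two directed edges are considered adjacent when they share at least one
endpoint (source-source, target-target, or cross); every edge is adjacent
to itself.  The resulting boolean matrix is exactly the adjacency structure
of the line graph plus the diagonal.  Batched masks additionally disallow
every entry that touches a padded token and never connect tokens from
different graphs.

Masks convert to additive form for use inside scaled-dot-product attention:
allowed pairs contribute 0, disallowed pairs a large finite negative value
(half of the most negative representable number at working precision —
finite so that an all-disallowed padded row still softmaxes to finite
values instead of NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "AttentionMask",
    "CorruptBatchError",
    "edge_adjacency_single",
    "edge_adjacency_batched",
    "node_adjacency_batched",
    "padding_mask",
    "to_additive",
    "ADDITIVE_DISALLOWED",
]

ADDITIVE_DISALLOWED = float(np.finfo(np.float64).min) / 2.0


class CorruptBatchError(ValueError):
    """Raised when an edge spans two graphs of a batch."""


@dataclass
class AttentionMask:
    """Pairwise-allowed matrix, (L, L) or batched (B, L, L).

    ``form`` is "boolean" (allowed: bool) or "additive" (0.0 for allowed,
    ``additive_value`` for disallowed).
    """

    allowed: np.ndarray
    form: Literal["boolean", "additive"] = "boolean"
    additive_value: float = ADDITIVE_DISALLOWED

    @property
    def shape(self):
        return self.allowed.shape


def edge_adjacency_single(edge_index: np.ndarray) -> AttentionMask:
    """Boolean (N_e, N_e) mask: edges sharing >= 1 endpoint may attend.

    Built with pure tensor operations: expand source/target id vectors to
    (N_e, N_e) and compare against their transposes for the four
    endpoint-sharing patterns.
    """
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(-1, 2)
    ne = edge_index.shape[0]
    if ne == 0:
        return AttentionMask(allowed=np.zeros((0, 0), dtype=bool))
    src = edge_index[:, 0][:, None]   # (N_e, 1)
    tgt = edge_index[:, 1][:, None]
    allowed = (src == src.T) | (tgt == tgt.T) | (src == tgt.T) | (tgt == src.T)
    return AttentionMask(allowed=allowed)


def edge_adjacency_batched(edge_index_cat: np.ndarray,
                           node_map: np.ndarray,
                           L: int) -> AttentionMask:
    """Batched (B, L, L) edge mask from a concatenated edge list.

    ``edge_index_cat`` uses batch-global node ids; ``node_map`` assigns each
    node to its graph.  Edges are laid out per graph in input order,
    left-aligned; entries touching padded slots are False.
    """
    edge_index_cat = np.asarray(edge_index_cat, dtype=np.int64).reshape(-1, 2)
    node_map = np.asarray(node_map, dtype=np.int64)
    B = int(node_map.max()) + 1 if node_map.size else 1
    if edge_index_cat.shape[0]:
        gsrc = node_map[edge_index_cat[:, 0]]
        gtgt = node_map[edge_index_cat[:, 1]]
        if np.any(gsrc != gtgt):
            raise CorruptBatchError("edge spans two graphs in the batch")
    else:
        gsrc = np.zeros(0, dtype=np.int64)
    # scatter global node ids into (B, L) slots; -1 sentinel for padding
    counts = np.bincount(gsrc, minlength=B)
    if L < counts.max(initial=0):
        raise CorruptBatchError(f"L={L} smaller than max edge count {counts.max()}")
    pos = _cumcount(gsrc)
    src_b = np.full((B, L), -1, dtype=np.int64)
    tgt_b = np.full((B, L), -2, dtype=np.int64)   # distinct sentinels
    src_b[gsrc, pos] = edge_index_cat[:, 0]
    tgt_b[gsrc, pos] = edge_index_cat[:, 1]
    s = src_b[:, :, None]
    t = tgt_b[:, :, None]
    sT = src_b[:, None, :]
    tT = tgt_b[:, None, :]
    allowed = (s == sT) | (t == tT) | (s == tT) | (t == sT)
    real = np.arange(L)[None, :] < counts[:, None]
    allowed &= real[:, :, None] & real[:, None, :]
    return AttentionMask(allowed=allowed)


def node_adjacency_batched(edge_index_cat: np.ndarray,
                           node_map: np.ndarray) -> AttentionMask:
    """Batched (B, N_max, N_max) node mask: adjacency plus self-attention.

    Entry (i, j) of slice b is True iff graph b contains edge (i, j) or
    (j, i), or i == j for a real node; padded positions are False.
    """
    edge_index_cat = np.asarray(edge_index_cat, dtype=np.int64).reshape(-1, 2)
    node_map = np.asarray(node_map, dtype=np.int64)
    B = int(node_map.max()) + 1 if node_map.size else 1
    node_counts = np.bincount(node_map, minlength=B)
    n_max = int(node_counts.max())
    offsets = np.concatenate([[0], np.cumsum(node_counts)[:-1]])
    allowed = np.zeros((B, n_max, n_max), dtype=bool)
    real = np.arange(n_max)[None, :] < node_counts[:, None]
    # diagonal for real nodes
    diag = np.arange(n_max)
    for b in range(B):
        allowed[b, diag[: node_counts[b]], diag[: node_counts[b]]] = True
    if edge_index_cat.shape[0]:
        gsrc = node_map[edge_index_cat[:, 0]]
        gtgt = node_map[edge_index_cat[:, 1]]
        if np.any(gsrc != gtgt):
            raise CorruptBatchError("edge spans two graphs in the batch")
        li = edge_index_cat[:, 0] - offsets[gsrc]
        lj = edge_index_cat[:, 1] - offsets[gsrc]
        allowed[gsrc, li, lj] = True
        allowed[gsrc, lj, li] = True
    allowed &= real[:, :, None] & real[:, None, :]
    return AttentionMask(allowed=allowed)


def padding_mask(pad: np.ndarray) -> AttentionMask:
    """(B, L, L) mask allowing attention only between real tokens."""
    pad = np.asarray(pad, dtype=bool)
    allowed = pad[:, :, None] & pad[:, None, :]
    return AttentionMask(allowed=allowed)


def to_additive(m: AttentionMask,
                additive_value: float = ADDITIVE_DISALLOWED) -> AttentionMask:
    """Boolean mask -> additive mask (0.0 allowed, large negative disallowed)."""
    if m.form != "boolean":
        raise ValueError("mask is already in additive form")
    add = np.where(m.allowed, 0.0, additive_value)
    return AttentionMask(allowed=add, form="additive", additive_value=additive_value)


def _cumcount(groups: np.ndarray) -> np.ndarray:
    """Position of each element within its group, in appearance order."""
    if groups.size == 0:
        return np.zeros(0, dtype=np.int64)
    pos = np.zeros(groups.size, dtype=np.int64)
    counters: dict[int, int] = {}
    for i, g in enumerate(groups):
        c = counters.get(int(g), 0)
        pos[i] = c
        counters[int(g)] = c + 1
    return pos
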