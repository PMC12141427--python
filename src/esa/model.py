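"""Layer-order config grammar and the full graph-level / node-level models.

A model is specified by a string over the alphabet {M, S, P}: M is a masked
attention block, S a plain self-attention block, P the attention-pooling
module.  Graph-level tasks require exactly one P; every S after the P
becomes one of the pooling module's internal refinement SABs.  Node-level
tasks use the encoder alone (no P).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import List, Literal, Optional, Sequence

import numpy as np

from . import graph_core, masking
from .attention import (MAB, PMA, SAB, AttentionParams, Linear, MLP, Module,
                        Tensor, pool_seeds)
from .autograd import no_grad

__all__ = ["ModelConfig", "ConfigError", "parse_config", "EsaModel",
           "esa_forward", "nsa_forward", "prepare_batch"]


class ConfigError(ValueError):
    """Raised for layer strings that violate the {M, S, P} grammar."""


@dataclass
class ModelConfig:
    layer_string: str = "MSP"
    hidden_dim: int = 64
    num_heads: int = 4
    k_seeds: int = 32
    norm_kind: Literal["layer", "batch"] = "layer"
    norm_placement: Literal["pre", "post"] = "pre"
    mlp_variant: Literal["standard", "gated"] = "standard"
    dropout: float = 0.0
    task: Literal["graph_regression", "graph_classification",
                  "node_classification"] = "graph_regression"
    out_dim: int = 1
    token_mode: Literal["edge", "node"] = "edge"
    seed_pooling: Literal["mean", "sum"] = "mean"

    @property
    def is_graph_level(self) -> bool:
        return self.task.startswith("graph")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ParsedPlan:
    encoder: List[str]       # sequence over {M, S}
    use_pma: bool
    p: int                   # number of SABs inside the pooling module


def parse_config(layer_string: str, task: str) -> ParsedPlan:
    """Parse a layer-order string, validating the grammar for the task."""
    s = "".join(layer_string.split()).upper()
    if not s:
        raise ConfigError("empty layer string")
    bad = set(s) - set("MSP")
    if bad:
        raise ConfigError(f"unknown layer characters {sorted(bad)}")
    n_p = s.count("P")
    graph_level = task.startswith("graph")
    if graph_level:
        if n_p != 1:
            raise ConfigError(
                f"graph-level config needs exactly one P, got {n_p}")
        idx = s.index("P")
        encoder, tail = s[:idx], s[idx + 1:]
        if any(c != "S" for c in tail):
            raise ConfigError("only S blocks may follow P")
        return ParsedPlan(encoder=list(encoder), use_pma=True, p=len(tail))
    if n_p != 0:
        raise ConfigError("node-level config must not contain P")
    return ParsedPlan(encoder=list(s), use_pma=False, p=0)


class EsaModel(Module):
    """Input embedding -> interleaved encoder -> optional PMA -> output head."""

    def __init__(self, config: ModelConfig, token_width: int,
                 seed: int | np.random.Generator = 0):
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        self.config = config
        self.token_width = token_width
        self.plan = parse_config(config.layer_string, config.task)
        params = AttentionParams(
            hidden_dim=config.hidden_dim, num_heads=config.num_heads,
            mlp_variant=config.mlp_variant, norm_kind=config.norm_kind,
            norm_placement=config.norm_placement, dropout=config.dropout)
        self.attn_params = params
        self.embed = Linear(token_width, config.hidden_dim, rng)
        self.blocks = [
            MAB(params, rng) if c == "M" else SAB(params, rng)
            for c in self.plan.encoder
        ]
        self.pma = (PMA(params, config.k_seeds, self.plan.p, rng)
                    if self.plan.use_pma else None)
        self.head_fc1 = Linear(config.hidden_dim, config.hidden_dim, rng)
        self.head_fc2 = Linear(config.hidden_dim, config.out_dim, rng)
        self._record: Optional[list] = None
        self._rng = rng

    # -- attention recording ----------------------------------------------

    def record_attention(self, on: bool = True) -> None:
        self._record = [] if on else None

    @property
    def recorded_attention(self) -> Optional[list]:
        return self._record

    # -- forward -----------------------------------------------------------

    def _head(self, x: Tensor) -> Tensor:
        return self.head_fc2(self.head_fc1(x).gelu())

    def forward(self, tokens: np.ndarray, pad: np.ndarray,
                adjacency: masking.AttentionMask) -> Tensor:
        """Run the model on a padded token batch.

        ``adjacency`` is the boolean adjacency mask matching the token mode
        (edge mask for edge tokens, node mask for node tokens).  Returns
        per-graph rows (graph tasks) or per-token rows (node tasks, padded
        positions included — strip with ``pad``).
        """
        if self._record is not None:
            self._record.clear()
        B, L, _ = tokens.shape
        if L == 0:
            # whole batch of edgeless graphs: single zero token, all padding
            tokens = np.zeros((B, 1, self.token_width))
            pad = np.zeros((B, 1), dtype=bool)
            adjacency = masking.AttentionMask(np.zeros((B, 1, 1), dtype=bool))
            L = 1
        adj_add = masking.to_additive(adjacency).allowed[:, None]       # (B,1,L,L)
        pad_pair = masking.to_additive(masking.padding_mask(pad)).allowed[:, None]
        key_add = np.where(pad, 0.0, masking.ADDITIVE_DISALLOWED)[:, None, None, :]
        pad_f = Tensor(pad.astype(np.float64)[..., None])

        x0 = self.embed(Tensor(tokens)) * pad_f
        h = x0
        for block in self.blocks:
            m = adj_add if isinstance(block, MAB) and not isinstance(block, SAB) \
                else pad_pair
            h = block(h, m, pad=pad, record=self._record, rng=self._rng)
            h = h * pad_f
        if self.pma is not None:
            z = h + x0                       # residual in embedding space
            z = z * pad_f
            pooled = self.pma(z, key_add, record=self._record, rng=self._rng)
            rep = pool_seeds(pooled, self.config.seed_pooling)
            return self._head(rep)
        return self._head(h)


def prepare_batch(graphs: Sequence[graph_core.Graph], config: ModelConfig):
    """Batch graphs and build the adjacency mask matching the token mode."""
    batch = graph_core.batch_graphs(graphs, tokenizer=config.token_mode)
    if config.token_mode == "edge":
        adj = masking.edge_adjacency_batched(
            batch.edge_index_cat, batch.node_map, batch.max_len)
    else:
        adj = masking.node_adjacency_batched(batch.edge_index_cat, batch.node_map)
    return batch, adj


def esa_forward(graphs: Sequence[graph_core.Graph], model: EsaModel) -> np.ndarray:
    """Per-graph predictions, (B, out_dim)."""
    if not model.config.is_graph_level:
        raise ConfigError("esa_forward requires a graph-level config")
    batch, adj = prepare_batch(graphs, model.config)
    with no_grad():
        out = model.forward(batch.tokens, batch.pad, adj)
    return out.data


def nsa_forward(graphs: Sequence[graph_core.Graph], model: EsaModel) -> np.ndarray:
    """Per-node predictions in input node order, (total_nodes, out_dim)."""
    if model.config.is_graph_level:
        raise ConfigError("nsa_forward requires a node-level config")
    if model.config.token_mode != "node":
        raise ConfigError("nsa_forward requires node tokens")
    batch, adj = prepare_batch(graphs, model.config)
    with no_grad():
        out = model.forward(batch.tokens, batch.pad, adj)
    return out.data[batch.pad]


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: EsaModel, path: str) -> None:
    """Parameter archive (.npz) plus a JSON sidecar with the config."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    np.savez(path, **arrays)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"config": asdict(model.config),
                   "token_width": model.token_width}, fh, indent=2)


def load_checkpoint(path: str) -> EsaModel:
    sidecar = str(path) + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    config = ModelConfig(**meta["config"])
    model = EsaModel(config, meta["token_width"])
    npz_path = path if str(path).endswith(".npz") else str(path) + ".npz"
    import os
    if not os.path.exists(npz_path):
        npz_path = path
    arrays = np.load(npz_path)
    params = dict(model.named_parameters())
    for name in arrays.files:
        params[name].data = arrays[name].copy()
    return model
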