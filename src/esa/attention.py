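"""Masked scaled-dot-product attention and the MAB / SAB / PMA blocks.

All blocks operate on batched token tensors of shape (B, L, d) and take
additive masks broadcastable to (B, 1, L_q, L_k).  SAB is literally MAB
with a zero mask (same code path).  PMA cross-attends k learnable seed
vectors to the token set and refines the result with p SABs, yielding a
permutation-invariant pooled representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, List, Literal, Optional

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "AttentionParams",
    "Module",
    "Linear",
    "LayerNorm",
    "MaskedBatchNorm",
    "MLP",
    "MultiHeadAttention",
    "MAB",
    "SAB",
    "PMA",
    "masked_sdpa",
    "pool_seeds",
]


@dataclass
class AttentionParams:
    """Hyperparameters shared by all attention blocks."""

    hidden_dim: int = 64
    num_heads: int = 4
    mlp_variant: Literal["standard", "gated"] = "standard"
    mlp_expansion: int = 2
    norm_kind: Literal["layer", "batch"] = "layer"
    norm_placement: Literal["pre", "post"] = "pre"
    dropout: float = 0.0

    def __post_init__(self):
        if self.hidden_dim % self.num_heads != 0:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} not divisible by "
                f"num_heads {self.num_heads}")

    @property
    def key_dim(self) -> int:
        return self.hidden_dim // self.num_heads


class Module:
    """Base class with recursive parameter discovery."""

    training: bool = True

    def parameters(self) -> Iterator[Parameter]:
        seen = set()
        for v in self.__dict__.values():
            yield from _params_of(v, seen)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for k, v in self.__dict__.items():
            yield from _named_params_of(v, f"{prefix}{k}", set())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in self.__dict__.values():
            for m in _modules_of(v):
                m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)


def _params_of(v, seen):
    if isinstance(v, Parameter):
        if id(v) not in seen:
            seen.add(id(v))
            yield v
    elif isinstance(v, Module):
        for p in v.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _params_of(item, seen)


def _named_params_of(v, name, seen):
    if isinstance(v, Parameter):
        yield name, v
    elif isinstance(v, Module):
        yield from v.named_parameters(prefix=name + ".")
    elif isinstance(v, (list, tuple)):
        for i, item in enumerate(v):
            yield from _named_params_of(item, f"{name}.{i}", seen)


def _modules_of(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _modules_of(item)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / math.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor, pad: Optional[np.ndarray] = None) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gain + self.shift


class MaskedBatchNorm(Module):
    """Feature-wise normalization over all real tokens in the batch.

    Statistics are computed per forward pass (no running averages); padded
    tokens are excluded via the pad indicator.
    """

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor, pad: Optional[np.ndarray] = None) -> Tensor:
        if pad is None:
            n = float(np.prod(x.shape[:-1]))
            w = None
        else:
            w = Tensor(pad.astype(np.float64)[..., None])
            n = float(pad.sum())
        if w is None:
            mu = x.mean(axis=tuple(range(x.ndim - 1)), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=tuple(range(x.ndim - 1)), keepdims=True)
        else:
            mu = (x * w).sum(axis=tuple(range(x.ndim - 1)), keepdims=True) * (1.0 / n)
            xc = x - mu
            var = (xc * xc * w).sum(axis=tuple(range(x.ndim - 1)), keepdims=True) * (1.0 / n)
        return xc / (var + self.eps).sqrt() * self.gain + self.shift


def _make_norm(params: AttentionParams) -> Module:
    if params.norm_kind == "layer":
        return LayerNorm(params.hidden_dim)
    return MaskedBatchNorm(params.hidden_dim)


class MLP(Module):
    """Two-layer feed-forward block; standard (GELU) or gated (SwiGLU-like)."""

    def __init__(self, dim: int, params: AttentionParams, rng: np.random.Generator):
        hidden = params.mlp_expansion * dim
        self.variant = params.mlp_variant
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        if self.variant == "gated":
            self.gate = Linear(dim, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if self.variant == "gated":
            return self.fc2(self.fc1(x).silu() * self.gate(x))
        return self.fc2(self.fc1(x).gelu())


def masked_sdpa(q: Tensor, k: Tensor, v: Tensor,
                mask_additive: Optional[np.ndarray] = None,
                record: Optional[list] = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k) + M) V, computed densely.

    ``mask_additive`` must broadcast against the (..., L_q, L_k) score
    matrix; 0 keeps a score, a large negative value censors it.
    """
    dk = q.shape[-1]
    if k.shape[-1] != dk or v.shape[-2] != k.shape[-2]:
        raise ValueError("query/key/value shape mismatch")
    scores = q.matmul(k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk))
    if mask_additive is not None:
        scores = scores + Tensor(mask_additive)
    attn = scores.softmax(axis=-1)
    if record is not None:
        record.append(attn.data.copy())
    return attn.matmul(v)


class MultiHeadAttention(Module):
    """h parallel masked SDPA heads on projected inputs, then output-projected."""

    def __init__(self, params: AttentionParams, rng: np.random.Generator):
        d = params.hidden_dim
        self.params = params
        self.w_q = Linear(d, d, rng)
        self.w_k = Linear(d, d, rng)
        self.w_v = Linear(d, d, rng)
        self.w_o = Linear(d, d, rng)

    def _split(self, x: Tensor) -> Tensor:
        # (B, L, d) -> (B, h, L, d_k)
        b, l, d = x.shape
        h = self.params.num_heads
        return x.reshape(b, l, h, d // h).transpose(0, 2, 1, 3)

    def __call__(self, x_q: Tensor, x_kv: Tensor,
                 mask_additive: Optional[np.ndarray] = None,
                 record: Optional[list] = None) -> Tensor:
        b, lq, d = x_q.shape
        q = self._split(self.w_q(x_q))
        k = self._split(self.w_k(x_kv))
        v = self._split(self.w_v(x_kv))
        out = masked_sdpa(q, k, v, mask_additive, record=record)
        out = out.transpose(0, 2, 1, 3).reshape(b, lq, d)
        return self.w_o(out)


def _dropout(x: Tensor, rate: float, training: bool,
             rng: Optional[np.random.Generator]) -> Tensor:
    if not training or rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * Tensor(keep)


class MAB(Module):
    """Masked self-attention block with residual connections.

    Pre-norm: H = Norm(X) + MultiHead(Norm(X), ..., M); out = H + MLP(Norm(H)).
    Post-norm applies normalization after each residual sum instead.
    """

    def __init__(self, params: AttentionParams, rng: np.random.Generator):
        self.params = params
        self.attn = MultiHeadAttention(params, rng)
        self.norm1 = _make_norm(params)
        self.norm2 = _make_norm(params)
        self.mlp = MLP(params.hidden_dim, params, rng)

    def __call__(self, x: Tensor, mask_additive: Optional[np.ndarray] = None,
                 pad: Optional[np.ndarray] = None,
                 record: Optional[list] = None,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
        drop = lambda t: _dropout(t, self.params.dropout, self.training, rng)
        if self.params.norm_placement == "pre":
            xb = self.norm1(x, pad=pad)
            h = xb + drop(self.attn(xb, xb, mask_additive, record=record))
            return h + drop(self.mlp(self.norm2(h, pad=pad)))
        h = self.norm1(x + drop(self.attn(x, x, mask_additive, record=record)), pad=pad)
        return self.norm2(h + drop(self.mlp(h)), pad=pad)


class SAB(MAB):
    """Self-attention block: a MAB evaluated with a zero (or padding) mask."""

    def __call__(self, x: Tensor, mask_additive: Optional[np.ndarray] = None,
                 pad: Optional[np.ndarray] = None,
                 record: Optional[list] = None,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
        # mask_additive, when given, must encode padding only
        return super().__call__(x, mask_additive, pad=pad, record=record, rng=rng)


class PMA(Module):
    """Pooling by multi-head attention with k learnable seeds.

    S_bar = Norm(MultiHead(S_k, Z, Z, padding mask)); the output is
    SAB^p(S_bar + MLP(S_bar)), k rows per graph.
    """

    def __init__(self, params: AttentionParams, k: int, p: int,
                 rng: np.random.Generator):
        if k < 1:
            raise ValueError("seed count k must be >= 1")
        self.params = params
        self.k = k
        self.seeds = Parameter(rng.standard_normal((k, params.hidden_dim)))
        self.attn = MultiHeadAttention(params, rng)
        self.norm = _make_norm(params)
        self.mlp = MLP(params.hidden_dim, params, rng)
        self.sabs = [SAB(params, rng) for _ in range(p)]

    def __call__(self, z: Tensor, key_mask_additive: Optional[np.ndarray] = None,
                 record: Optional[list] = None,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
        b = z.shape[0]
        s = self.seeds.reshape(1, self.k, self.params.hidden_dim)
        s = s.broadcast_to((b, self.k, self.params.hidden_dim))
        s_bar = self.norm(self.attn(s, z, key_mask_additive, record=record))
        out = s_bar + self.mlp(s_bar)
        for sab in self.sabs:
            out = sab(out, None, record=record, rng=rng)
        return out


def pool_seeds(pma_out: Tensor, how: Literal["mean", "sum"] = "mean") -> Tensor:
    """Aggregate the k seed rows into one vector per graph."""
    if how == "mean":
        return pma_out.mean(axis=-2)
    if how == "sum":
        return pma_out.sum(axis=-2)
    raise ValueError(f"unknown pooling {how!r}")
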