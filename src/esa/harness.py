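"""Training loop, evaluation metrics, and attention-score analysis."""

from __future__ import annotations

import copy
import json
import math
import time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np

from . import graph_core, masking
from .attention import Tensor
from .autograd import no_grad
from .model import EsaModel, ModelConfig, prepare_batch

__all__ = [
    "OptConfig",
    "RunRecord",
    "Adam",
    "matthews_cc",
    "regression_metrics",
    "gini",
    "extract_attention",
    "train",
    "evaluate",
]


# -- metrics ----------------------------------------------------------------

def matthews_cc(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Matthews correlation coefficient, generalized multiclass form.

    Computed from the confusion matrix C as
    ``(c*s - sum_k t_k p_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))``
    where c = trace(C), s = total samples, t_k / p_k are true / predicted
    class totals.  Returns 0.0 when the denominator vanishes (e.g. a
    constant predictor).
    """
    y_true = np.asarray(y_true).astype(np.int64).ravel()
    y_pred = np.asarray(y_pred).astype(np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    conf = np.zeros((k, k), dtype=np.float64)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    s = conf.sum()
    c = np.trace(conf)
    t_k = conf.sum(axis=1)
    p_k = conf.sum(axis=0)
    num = c * s - (t_k * p_k).sum()
    den = math.sqrt(max(s * s - (p_k ** 2).sum(), 0.0)) * \
        math.sqrt(max(s * s - (t_k ** 2).sum(), 0.0))
    if den == 0.0:
        return 0.0
    return float(num / den)


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Dict[str, float]:
    """MAE, RMSE and R^2 = 1 - SSE/SST (NaN with a warning for constant y)."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    err = y_pred - y_true
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("constant y_true: R^2 undefined", RuntimeWarning)
        r2 = float("nan")
    else:
        r2 = float(1.0 - (err ** 2).sum() / sst)
    return {"MAE": mae, "RMSE": rmse, "R2": r2}


def gini(scores: np.ndarray) -> float:
    """Gini coefficient of a nonnegative vector.

    Equals ``sum_ij |x_i - x_j| / (2 n^2 mean)``: 0 for a uniform vector,
    (n-1)/n for a one-hot vector, approaching 1 in the large-n limit.
    """
    x = np.asarray(scores, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    if np.any(x < 0):
        raise ValueError("scores must be nonnegative")
    total = x.sum()
    if total == 0.0:
        raise ValueError("all-zero input has undefined Gini")
    xs = np.sort(x)
    n = x.size
    # sorted form of the pairwise-difference formula
    return float((2.0 * np.arange(1, n + 1) - n - 1).dot(xs) / (n * total))


def extract_attention(model: EsaModel, graphs: Sequence[graph_core.Graph],
                      layer_index: Optional[int] = None,
                      head_average: bool = False):
    """Post-softmax attention scores from a forward pass in recording mode.

    Returns the list of per-layer (B, h, L_q, L_k) arrays, or the requested
    layer; with ``head_average`` the head axis is meaned away.
    """
    model.record_attention(True)
    try:
        batch, adj = prepare_batch(graphs, model.config)
        with no_grad():
            model.forward(batch.tokens, batch.pad, adj)
        scores = [s.copy() for s in model.recorded_attention]
    finally:
        model.record_attention(False)
    if head_average:
        scores = [s.mean(axis=1) for s in scores]
    if layer_index is None:
        return scores
    if not (0 <= layer_index < len(scores)):
        raise IndexError(f"layer_index {layer_index} out of range "
                         f"[0, {len(scores)})")
    return scores[layer_index]


# -- optimization -----------------------------------------------------------

@dataclass
class OptConfig:
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 20
    grad_clip: float = 5.0
    seed: int = 0


class Adam:
    def __init__(self, params, config: OptConfig):
        self.params = list(params)
        self.cfg = config
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.cfg.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.cfg.weight_decay:
                g = g + self.cfg.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.cfg.lr * mhat / (np.sqrt(vhat) + self.cfg.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class RunRecord:
    config: dict
    seed: int
    epochs: List[dict] = field(default_factory=list)
    final_test: Dict[str, float] = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# -- loss / batching helpers ------------------------------------------------

def _graph_targets(graphs) -> np.ndarray:
    return np.stack([np.atleast_1d(g.y) for g in graphs])


def _node_targets(graphs) -> np.ndarray:
    return np.concatenate([np.asarray(g.y).ravel() for g in graphs])


def _batch_loss(model: EsaModel, graphs) -> Tensor:
    cfg = model.config
    batch, adj = prepare_batch(graphs, cfg)
    out = model.forward(batch.tokens, batch.pad, adj)
    if cfg.task == "graph_regression":
        y = Tensor(_graph_targets(graphs))
        diff = out - y
        return (diff * diff).mean()
    if cfg.task == "graph_classification":
        y = _graph_targets(graphs).ravel().astype(np.int64)
        logp = out.log_softmax(axis=-1)
        picked = logp[np.arange(len(graphs)), y]
        return -picked.mean()
    # node classification: cross-entropy over real tokens
    y = _node_targets(graphs).astype(np.int64)
    logp = out.log_softmax(axis=-1)
    b_idx, l_idx = np.nonzero(batch.pad)
    picked = logp[b_idx, l_idx, y]
    return -picked.mean()


def _grad_norm_clip(model: EsaModel, clip: float) -> None:
    if clip <= 0:
        return
    total = 0.0
    params = list(model.parameters())
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if norm > clip:
        scale = clip / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def evaluate(model: EsaModel, graphs, batch_size: int = 64) -> Dict[str, float]:
    """Task-appropriate metrics on a list of graphs."""
    cfg = model.config
    model.eval()
    preds, trues = [], []
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start:start + batch_size]
        batch, adj = prepare_batch(chunk, cfg)
        with no_grad():
            out = model.forward(batch.tokens, batch.pad, adj).data
        if cfg.task == "graph_regression":
            preds.append(out)
            trues.append(_graph_targets(chunk))
        elif cfg.task == "graph_classification":
            preds.append(out.argmax(axis=-1))
            trues.append(_graph_targets(chunk).ravel())
        else:
            preds.append(out[batch.pad].argmax(axis=-1))
            trues.append(_node_targets(chunk))
    model.train()
    pred = np.concatenate(preds)
    true = np.concatenate(trues)
    if cfg.task == "graph_regression":
        return regression_metrics(true.ravel(), pred.ravel())
    return {"MCC": matthews_cc(true.astype(np.int64), pred.astype(np.int64)),
            "accuracy": float((true.astype(np.int64) == pred).mean())}


def train(model: EsaModel, data: Dict[str, list],
          opt_config: Optional[OptConfig] = None,
          verbose: bool = False) -> RunRecord:
    """Mini-batch training with early stopping on validation loss.

    ``data`` maps "train" / "val" / "test" (val and test optional) to graph
    lists.  The best-validation parameter set is restored before the final
    test evaluation.  Deterministic given ``opt_config.seed``.
    """
    cfg = opt_config or OptConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg)
    record = RunRecord(config={"model": asdict(model.config),
                               "opt": asdict(cfg)},
                       seed=cfg.seed)
    train_set = list(data["train"])
    val_set = data.get("val")
    best_val = math.inf
    best_params = None
    bad_epochs = 0
    t0 = time.time()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            chunk = [train_set[i] for i in order[start:start + cfg.batch_size]]
            opt.zero_grad()
            loss = _batch_loss(model, chunk)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={cfg.lr}, mask={masking.ADDITIVE_DISALLOWED:.3g})")
            loss.backward()
            _grad_norm_clip(model, cfg.grad_clip)
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_set:
            val_loss = float(np.mean([
                _eval_loss(model, val_set[i:i + cfg.batch_size])
                for i in range(0, len(val_set), cfg.batch_size)]))
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = [p.data.copy() for p in model.parameters()]
                bad_epochs = 0
            else:
                bad_epochs += 1
        record.epochs.append(entry)
        if verbose:
            print(json.dumps(entry))
        if val_set and bad_epochs >= cfg.patience:
            break
    if best_params is not None:
        for p, best in zip(model.parameters(), best_params):
            p.data = best
    if data.get("test"):
        record.final_test = evaluate(model, data["test"], cfg.batch_size)
    record.wall_clock_s = time.time() - t0
    return record


def _eval_loss(model: EsaModel, graphs) -> float:
    model.eval()
    with no_grad():
        val = float(_batch_loss(model, graphs).data)
    model.train()
    return val
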