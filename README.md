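# esa-graph

Edge-set attention (ESA) for learning on graphs: a graph is treated as a
**set of edge tokens** (source-node features ∥ target-node features ∥ edge
features), processed by a stack of interleaved **masked** and vanilla
self-attention blocks, followed by **attention-based pooling** over a small
set of learnable seed vectors for graph-level predictions. A node-token
variant (**NSA**) with a node-adjacency mask and no pooling block handles
node-level tasks.

The package is pure scientific Python (NumPy/SciPy). Because no deep-learning
framework is assumed, the blocks run on a small reverse-mode automatic
differentiation engine included in the package (`esa.autograd`), verified
against finite differences.

## Layout

| module | contents |
| --- | --- |
| `esa.graph_core` | `Graph`/`TokenBatch` data model, edge-token construction, batching, radius graphs, Gaussian distance basis, JSON-lines IO |
| `esa.masking` | edge- and node-adjacency attention masks (single and batched), additive-form conversion |
| `esa.attention` | masked scaled-dot-product attention, multi-head wrapper, MAB / SAB / PMA blocks, seed pooling |
| `esa.model` | `{M,S,P}` layer-string grammar, `EsaModel`, graph-level (`esa_forward`) and node-level (`nsa_forward`) pipelines, checkpoints |
| `esa.synthetic_data` | seeded Erdős–Rényi generators, triangle/edge counting targets, BFS-distance node labels, 1-WL color refinement, WL fixture pair |
| `esa.harness` | Adam training loop with early stopping, MCC / MAE / RMSE / R² / Gini metrics, attention-score extraction |

## CLI

```bash
# generate synthetic datasets (JSON lines + manifest)
esa synth --generator counting --target triangle_count \
    --n-graphs 500 --n-min 6 --n-max 12 --p-edge 0.35 --seed 0 --out tri.jsonl

# train from a YAML config (model / opt / data sections)
esa train --config cfg.yaml --seed 0 --out-dir runs

# evaluate a checkpoint
esa eval --checkpoint runs/ckpt_<hash>_<seed>.npz --data tri.jsonl
```

Example `cfg.yaml`:

```yaml
model:
  layer_string: MSPS      # M = masked block, S = self-attention, P = pooling
  hidden_dim: 64
  num_heads: 4
  k_seeds: 32
  task: graph_regression
  out_dim: 1
opt:
  lr: 1.0e-3
  max_epochs: 50
  batch_size: 32
data:
  path: tri.jsonl
  fractions: [0.8, 0.1]   # train/val; remainder is test
```

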