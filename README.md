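# drugformer

Per-cell drug-resistance prediction from single-cell RNA-seq, using a
graph-augmented transformer.

Tumors contain subpopulations of cells that tolerate a drug and seed
relapse.  Given scRNA-seq profiles with per-cell "resistant"/"sensitive"
labels, this package trains a classifier that fuses two views of each cell:

* **a token path** — the cell's top-N₁ expressed genes, serialized in rank
  order and encoded by a stack of transformer encoder blocks
  (multi-head attention softmax(QKᵀ/C)V with C = √head_dim, residual +
  LayerNorm, ReLU feed-forward);
* **a graph path** — a gene knowledge graph built from dosage-sensitivity
  scores (pHaplo/pTriplo; genes are joined when their score pairs lie
  within distance τ), encoded by graph attention:
  e_ij = LeakyReLU(aᵀ[W¹gᵢ ‖ W¹gⱼ]), α = softmax over N(i) ∪ {i},
  g′ᵢ = ReLU(Σⱼ α_ij W²gⱼ).

Gated aggregators fuse the two paths per token position
(Z_f = ReLU([t ‖ g̃] W₃ + b₃)); a bottleneck head maps the flattened final
representation to (p_resistant, p_sensitive), trained with two-component
binary cross-entropy under five-fold cross-validation.  A synthetic-data
generator with a planted resistance signature makes the whole pipeline
testable without any external download.  See `docs/methods.md` for the full
model description and design conventions.

The model itself runs on a compact NumPy reverse-mode autodiff engine
(`drugformer.autograd`), verified against finite differences — no GPU
framework required.

## Worked example

```python
import drugformer as df

dataset = df.generate_dataset(df.SyntheticConfig(
    n_cells=200, n_genes=150, n_signature_genes=15,
    effect_size=3.0, score_cluster_spread=0.0, seed=0))
graph = df.build_graph(dataset.scores, tau=0.05)

report = df.cross_validate(
    dataset, graph,
    df.ModelConfig(embed_dim=32, n_heads=4, n_tokens=32,
                   encoder_count=2, ffn_hidden=64),
    df.TrainConfig(batch_size=64, epochs=5, folds=5, seed=0))
print(", ".join(f"{k}={v:.3f}" for k, v in report.mean.items()))
```

prints (about half a minute on one CPU):

```
accuracy=0.675, precision=0.701, recall=0.686, f1=0.664, auc=0.780
```

Each number is the unweighted mean over the five held-out folds; AUC well
above 0.5 means the model recovered the planted 3-fold signature shift
through rank serialization alone (the classifier never sees expression
magnitudes).  Larger benchmarks separate more cleanly — at 400 cells × 300
genes the same architecture reaches mean AUC ≈ 0.95–0.97 (run
`scripts/acceptance.py` below).  The scripts in `examples/` walk through
each capability: simulation, graph construction, tokenization,
cross-validated training, and the ablation/baseline comparison.

A command-line interface mirrors the library for shell use:

```
drugformer simulate --n-cells 400 --n-genes 300 --effect 3.0 --seed 1 --out-dir data/
drugformer build-graph --scores data/scores.tsv --tau 0.05 --out graph/
drugformer train --expression data/matrix.mtx --labels data/labels.tsv \
    --scores data/scores.tsv --config run.yaml --out run/
```

Every run writes a `manifest.json` (config, seed, versions, input digests)
for reproducibility; identical seeds reproduce loss traces and predictions
bit-identically.

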