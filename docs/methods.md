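# Methods

## The prediction problem

Tumors are heterogeneous: within one lesion, some cancer-cell subpopulations
tolerate a drug while others die, and the tolerant lineages drive relapse.
Given single-cell RNA-seq profiles of cells with known drug-response labels
("resistant" / "sensitive"), the task is a per-cell binary classifier that
generalizes to unlabeled cells, so resistant subpopulations can be mapped and
interrogated.

## Model

The classifier fuses two views of a cell.

**Token path.** Each cell is serialized as the ordered sequence of its
N₁ top-expressed genes (a gene-token "sentence"; expression magnitude is
discarded, only the identity and rank of genes survive).  Tokens receive a
learned semantic embedding plus a learned rank-position embedding, both of
dimension d, and pass through a stack of standard post-norm transformer
encoder blocks: multi-head scaled dot-product attention
softmax(QKᵀ/C)V with C = √(d/h), head concatenation and output projection,
residual + LayerNorm, a position-wise ReLU feed-forward sublayer, and a
second LayerNorm.

**Graph path.** Genes are nodes of a knowledge graph built from
dosage-sensitivity scores: pHaplo (probability of haploinsufficiency) and
pTriplo (probability of triplosensitivity).  Two genes are joined when the
Euclidean distance between their (pHaplo, pTriplo) pairs is at most τ
(default 0.05); an optional per-node cap keeps only each node's nearest
neighbors, re-symmetrized by union.  A graph attention layer computes
e_ij = LeakyReLU(aᵀ[W¹gᵢ ‖ W¹gⱼ]) over each node's neighborhood plus itself,
softmax-normalizes to attention coefficients α_ij, and emits
g′ᵢ = ReLU(Σⱼ α_ij W²gⱼ).  An isolated node attends only to itself.

**Fusion.** Node embeddings are aligned to the cell's token order (PAD
positions get zero rows) and fused with the token path by a gated
aggregator: per position, the two d-vectors are concatenated and projected
through ReLU(· W₃ + b₃) back to d.  The default six-block flow is: one
encoder, first fusion, four encoders, a second graph-attention layer (on
the first layer's embeddings, same adjacency) with a second fusion, and a
final encoder.  With E encoder blocks generally: 1 before the first fusion,
E − 2 between the fusions, 1 after the second.

**Head and loss.** The final N₁ × d representation is flattened (PAD rows
enter as zeros so the weight shape is static), compressed by a linear
bottleneck to 32 dimensions, and mapped by a 2-logit layer through an
elementwise sigmoid (default; softmax optional) to
(p_resistant, p_sensitive).  Training minimizes the two-component binary
cross-entropy against one-hot labels, probabilities clamped to
[1e-7, 1 − 1e-7]; the hard call thresholds p_resistant at 0.5.

## Conventions where the architecture leaves room

These points were genuinely open and are fixed here as package conventions:

* **Attention scaling.** Standard scaled dot-product with the defined key
  matrix, C = √head_dim.
* **Feed-forward residual.** The feed-forward sublayer adds its input
  (post-norm convention) before the second LayerNorm; `ffn_residual=False`
  selects the variant without it.
* **Encoder depth.** `encoder_count` is configurable (default 6), split
  around the two fusions as described above.
* **Second graph pass.** Its input node features are the first pass's
  embeddings over the same restricted gene set, so its transform weights
  are d × d.
* **Shared GAT weights.** W¹, W², and the attention vector a are shared
  across nodes, as is standard for graph attention.
* **Padding.** PAD tokens carry a learned embedding but receive and
  contribute zero attention weight; their rows are re-zeroed after every
  block and enter the flattened head as zeros.
* **Ranking key.** Cells are serialized on the expression values as given
  (raw counts or normalized values — the package does not normalize);
  ties break by ascending token id, which makes serialization
  deterministic across platforms.  Zero-expression genes are never
  tokenized, even if that leaves padding.
* **Output normalization.** Elementwise sigmoid by default; softmax is
  offered since one-hot targets make a normalized pair natural.
* **Initialization.** Scaled-uniform fan-in U(±1/√fan_in) for weights and
  embeddings, ones/zeros for LayerNorm gains/biases, fully seeded.
* **Graph/expression reconciliation.** The graph is restricted to the
  expression vocabulary before training: genes absent from the score table
  become isolated nodes with zero features (the graph path contributes only
  their self-term), and node order equals token-id order so alignment is a
  direct gather.

## Training protocol

Minibatch Adam with batch size 64 for 5 epochs, five-fold cross-validation:
cells are randomly partitioned into five disjoint folds of near-equal size
(sizes differ by at most one); each fold is scored by a model trained on
the other four, and metrics (accuracy, F1, precision, recall, AUC — the
resistant class is positive) are averaged unweighted over folds.  AUC is the
Mann–Whitney rank statistic, which credits ties between a positive and a
negative score with ½.  Per-fold metrics are averaged rather than pooled.

The default learning rate is 3e-3: at the desk-scale configurations this
package targets (a few dozen optimizer steps per fold), smaller rates leave
the model visibly under-converged within the 5-epoch budget.  The per-epoch
loss reported in traces is the cell-weighted mean over batches, so it is
invariant to how the shuffle cuts the final short batch.

**Reduced model ("graph-free" ablation).** Both graph-attention passes and
both fusions are removed, leaving a pure encoder stack of the same depth
with identical folds and seeds.  An alternative semantics — keeping the
fusion wiring but feeding zeroed node features — is available via
`ablation_mode="zero_graph"`.

**Baselines.** Random forest, SVM, and logistic regression
(scikit-learn defaults) on the flat expression matrix with the same folds;
they are comparison plumbing, not part of the method.

**Heterogeneity statistic.** Intra-tumoral heterogeneity of a sample is the
Shannon entropy −Σ p ln p of its inferred cell-state proportions
(0 ln 0 := 0): zero for a single state, ln k for k equally abundant states.

## Numerical core

No GPU framework is used: the model runs on a compact reverse-mode autodiff
engine over NumPy arrays (`drugformer.autograd`), with broadcasting-aware
backward rules, dedicated softmax/LayerNorm gradients, and an Adam
optimizer.  Every backward rule is verified against central finite
differences in the test suite, and full layers are verified against
independent straight-line reimplementations.  All computation is float64
and single-threaded, which makes runs bit-reproducible from their seeds.
Attention masking uses an additive −1e9 logit bias; masked softmax weights
underflow to exactly zero in float64.

## Synthetic benchmark

Real drug-annotated single-cell training corpora are large external
resources, so the package ships a generator that reproduces their
*statistical shape* with known ground truth:

* **Counts.** Gamma-Poisson (negative binomial, dispersion θ = 2) with
  log-normal gene-level means (ln-mean 0, ln-sd 1), giving sparse
  (roughly 40–50% zeros at the default scale) overdispersed matrices.
  UMI-style counts need no zero inflation beyond the negative binomial, so
  the extra independent-dropout knob `sparsity` defaults to 0.
* **Labels.** Exactly ⌊n_cells · resistant_fraction⌋ cells are resistant;
  the label vector is then seed-shuffled, so the count is exact and
  testable.
* **Signal.** Signature genes' means are multiplied by `effect_size` in
  resistant cells only.  Signature baselines are drawn from the expressed
  half of the gene-mean distribution (half-normal on the log scale):
  resistance markers are, by construction, detectably expressed genes —
  marker definitions in this field require detection in a substantial
  fraction of cells — and a fold change planted on a never-detected gene
  would be invisible to rank serialization.  `effect_size = 1` is the null:
  resistant and sensitive cells are then draws from the same distribution.
* **Scores.** Cluster centroids are placed in the (pHaplo, pTriplo) unit
  square by seeded dart-throwing with a minimum separation well above the
  within-cluster jitter (uniform ±spread per coordinate, clipped to [0,1];
  grid fallback when many clusters are requested), so score similarity
  recovers the clusters.  All signature genes sit inside a single cluster,
  giving the knowledge graph a planted community that connects them — the
  graph-structured signal the ablation comparison probes.

What the generator does **not** emulate: batch effects, doublets, library
size variation, ambient RNA, real gene–gene correlation structure, or the
composition of any real cohort.  Passing tests therefore demonstrate that
the implementation recovers planted structure under the stated statistical
model, not that the architecture attains any particular accuracy on real
tumors.

## Problem sizes and verification

The shipped verification (`scripts/acceptance.py`, `tests/`) uses
400 cells × 300 genes with a 20-gene signature at fold change 3, and a
small architecture (N₁ = 32, d = 32, h = 4, two encoder blocks around the
two fusions) — sizes at which five-fold cross-validation completes in
seconds on one CPU while every stage of the full flow is exercised.  At
these conditions the model reaches mean held-out AUC ≈ 0.95–0.97, the null
(effect 1) stays at chance, and the reduced model performs within a small
band of the full one: with 300 genes and a clean planted signature the
token path alone nearly saturates the task, so the graph path's
contribution is architectural rather than decisive at this scale.  The
classic baselines, which see the raw expression magnitudes that rank
serialization deliberately discards, are near-perfect on this easy
synthetic task — a property of the benchmark, not of the method ranking.

## Known limitations

* The flattened output head ties weights to rank positions; two cells with
  the same token set in different orders produce different head inputs.
  That is the architecture as specified, but it makes small-N₁
  configurations position-sensitive.
* Training is CPU-bound NumPy; configurations beyond ~10⁵ parameters or
  N₁ ≳ 256 become slow.  The engine is adequate for the shipped problem
  sizes, not a general deep-learning runtime.
* `compute_metrics` reports AUC as NaN when a fold contains a single class;
  fold means then average the defined folds only.
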