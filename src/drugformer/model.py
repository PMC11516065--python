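"""The DrugFormer network: transformer encoders over serialized gene tokens,
graph attention over the dosage-sensitivity knowledge graph, gated fusion of
the two paths, and a bottleneck classification head.

Data flow (default ``encoder_count = 6``)::

    T   = token embedding + position embedding          (N1 x d)
    T1  = Enc_1(T)
    G'  = GAT_1(node features, adjacency)               (N2 x d)
    Gt  = align(G', tokens)        # per-cell gather    (N1 x d)
    Z1  = GA_1(T1, Gt)             # gated fusion
    T2..T5 = Enc_2..Enc_5 applied sequentially
    G'' = GAT_2(G', adjacency)     # second graph pass, 256-dim features
    T6  = GA_2(T5, align(G'', tokens))
    T7  = Enc_6(T6)
    P   = head(T7)  ->  (p_resistant, p_sensitive)

With ``encoder_count = E`` the flow is: one encoder before the first fusion,
``E - 2`` encoders between the fusions, and one after the second fusion.
The ablated variant ("DrugFormer-") drops both graph passes and fusions and
runs the E encoders as a pure stack of the same depth.

Conventions chosen where the architecture description leaves room (recorded
in the methods note): attention uses the standard scaled dot product
softmax(Q K^T / C) V with C = sqrt(head_dim); the feed-forward sublayer adds
a residual connection before its layer norm by default (switchable); PAD
positions receive and contribute zero attention weight, their rows are
re-zeroed after every block, and they enter the flattened head as zeros so
the head's shape is static.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autograd import Tensor, concat
from .graph import KnowledgeGraph
from .tokenization import CellTokenSequence, GeneVocabulary, sequences_to_array

__all__ = [
    "ModelConfig",
    "ModelParams",
    "PredictionResult",
    "leaky_relu",
    "attention_head",
    "encoder_block",
    "gat_layer",
    "align_node_embeddings",
    "gated_aggregate",
    "output_head",
    "cross_entropy",
    "forward",
    "predict",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``attention_scale`` defaults to sqrt(head_dim); ``ffn_hidden`` defaults
    to 4 * embed_dim; ``gat_output_dim`` is tied to embed_dim so graph and
    token embeddings share a space.
    """

    embed_dim: int = 256
    n_heads: int = 8
    n_tokens: int = 2048
    ffn_hidden: int | None = None
    encoder_count: int = 6
    bottleneck_dim: int = 32
    leaky_slope: float = 0.2
    attention_scale: float | None = None
    layernorm_eps: float = 1e-5
    dropout: float = 0.0
    output_normalization: str = "sigmoid"  # or "softmax"
    ffn_residual: bool = True

    def __post_init__(self):
        if self.embed_dim <= 0 or self.n_heads <= 0 or self.n_tokens <= 0:
            raise ValueError("all counts must be positive")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.encoder_count < 1 or self.bottleneck_dim < 1:
            raise ValueError("all counts must be positive")
        if self.output_normalization not in ("sigmoid", "softmax"):
            raise ValueError("output_normalization must be 'sigmoid' or 'softmax'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @property
    def scale(self) -> float:
        return self.attention_scale if self.attention_scale is not None else float(np.sqrt(self.head_dim))

    @property
    def ffn_dim(self) -> int:
        return self.ffn_hidden if self.ffn_hidden is not None else 4 * self.embed_dim


class ModelParams:
    """All learnable weights, as a name -> Tensor mapping.

    Initialization is scaled-uniform fan-in U(+-1/sqrt(fan_in)) for weight
    matrices and embedding tables, ones for layer-norm gains, zeros for
    biases; fully determined by the seed.
    """

    def __init__(self, tensors: dict[str, Tensor]):
        self.tensors = tensors

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tensors

    def values(self) -> list[Tensor]:
        return list(self.tensors.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.tensors[k].data = np.asarray(v, dtype=np.float64).copy()

    @classmethod
    def init(
        cls,
        config: ModelConfig,
        vocab_size: int,
        feature_dim: int,
        seed: int = 0,
    ) -> "ModelParams":
        """Initialize all weights for a vocabulary of ``vocab_size`` real
        genes (the PAD embedding is one extra row) and graph node features of
        length ``feature_dim``."""
        rng = np.random.default_rng(seed)
        d = config.embed_dim
        t: dict[str, Tensor] = {}

        def uniform(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)

        def zeros(shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(shape):
            return Tensor(np.ones(shape), requires_grad=True)

        t["tok_emb"] = uniform((vocab_size + 1, d), d)
        t["pos_emb"] = uniform((config.n_tokens, d), d)
        for l in range(config.encoder_count):
            p = f"enc{l}_"
            for name in ("Wq", "Wk", "Wv", "Wo"):
                t[p + name] = uniform((d, d), d)
            for name in ("bq", "bk", "bv", "bo"):
                t[p + name] = zeros((d,))
            t[p + "W1"] = uniform((d, config.ffn_dim), d)
            t[p + "b1"] = zeros((config.ffn_dim,))
            t[p + "W2"] = uniform((config.ffn_dim, d), config.ffn_dim)
            t[p + "b2"] = zeros((d,))
            t[p + "ln1_g"] = ones((d,))
            t[p + "ln1_b"] = zeros((d,))
            t[p + "ln2_g"] = ones((d,))
            t[p + "ln2_b"] = zeros((d,))
        # first GAT layer transforms raw k-dim node features; the second
        # transforms the first layer's d-dim embeddings
        for l, in_dim in ((1, feature_dim), (2, d)):
            p = f"gat{l}_"
            t[p + "W1"] = uniform((in_dim, d), max(in_dim, 1))
            t[p + "W2"] = uniform((in_dim, d), max(in_dim, 1))
            t[p + "a"] = uniform((2 * d, 1), 2 * d)
        for l in (1, 2):
            t[f"ga{l}_W3"] = uniform((2 * d, d), 2 * d)
            t[f"ga{l}_b3"] = zeros((d,))
        t["out_W4"] = uniform((config.n_tokens * d, config.bottleneck_dim), config.n_tokens * d)
        t["out_b4"] = zeros((config.bottleneck_dim,))
        t["out_W5"] = uniform((config.bottleneck_dim, 2), config.bottleneck_dim)
        t["out_b5"] = zeros((2,))
        return cls(t)


@dataclass(frozen=True)
class PredictionResult:
    """Per-cell resistance probability and hard call (threshold 0.5)."""

    cell_id: str
    p_resistant: float
    p_sensitive: float
    call: str  # "resistant" or "sensitive"


def leaky_relu(x, slope: float = 0.2):
    """x for x > 0, slope * x otherwise (elementwise)."""
    if isinstance(x, Tensor):
        return x.leaky_relu(slope)
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x > 0, x, slope * x)
    return float(out) if out.ndim == 0 else out


_NEG = -1e9  # additive mask bias; softmax weight underflows to exactly 0 vs 1


def _masked_softmax(scores: Tensor, key_mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax with masked positions forced to zero weight.

    ``key_mask`` broadcasts over ``scores`` with 1 = keep, 0 = mask.
    """
    bias = Tensor((1.0 - key_mask) * _NEG)
    return (scores + bias).softmax(axis=axis)


def attention_head(
    T_h: Tensor | np.ndarray,
    mask: np.ndarray,
    Wq: Tensor,
    bq: Tensor,
    Wk: Tensor,
    bk: Tensor,
    Wv: Tensor,
    bv: Tensor,
    scale: float,
) -> Tensor:
    """Single attention head on an (n, head_dim) input.

    Computes row-softmax(Q K^T / scale) V with PAD positions receiving and
    contributing zero weight and zero output.
    """
    mask = np.asarray(mask, dtype=np.float64).reshape(-1)
    if mask.sum() == 0:
        raise ValueError("attention over an all-pad input is undefined")
    x = T_h if isinstance(T_h, Tensor) else Tensor(T_h)
    q = x @ Wq + bq
    k = x @ Wk + bk
    v = x @ Wv + bv
    scores = (q @ k.transpose(1, 0)) / scale
    attn = _masked_softmax(scores, mask[None, :])
    out = attn @ v
    return out * Tensor(mask[:, None])


def encoder_block(
    T: Tensor | np.ndarray,
    mask: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    prefix: str = "enc0_",
) -> Tensor:
    """One transformer encoder block on a (..., n, d) input.

    Multi-head scaled dot-product attention, concat + output projection,
    residual + layer norm, position-wise feed-forward (ReLU), then the second
    layer norm (with or without a feed-forward residual per config).  PAD
    rows are re-zeroed on output.
    """
    x = T if isinstance(T, Tensor) else Tensor(T)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("encoder input contains non-finite values")
    batched = x.ndim == 3
    if not batched:
        x = x.reshape(1, *x.shape)
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim == 1:
        mask = mask[None, :]
    B, n, d = x.shape
    h, dh = config.n_heads, config.head_dim

    def project(W, b):
        y = x @ params[prefix + W] + params[prefix + b]
        return y.reshape(B, n, h, dh).transpose(0, 2, 1, 3)  # (B, h, n, dh)

    q, k, v = project("Wq", "bq"), project("Wk", "bk"), project("Wv", "bv")
    scores = (q @ k.transpose(0, 1, 3, 2)) / config.scale
    attn = _masked_softmax(scores, mask[:, None, None, :])
    z = (attn @ v).transpose(0, 2, 1, 3).reshape(B, n, d)
    z = z * Tensor(mask[:, :, None])
    z = z @ params[prefix + "Wo"] + params[prefix + "bo"]

    zp = (x + z).layernorm(config.layernorm_eps)
    zp = zp * params[prefix + "ln1_g"] + params[prefix + "ln1_b"]

    f = (zp @ params[prefix + "W1"] + params[prefix + "b1"]).relu()
    f = f @ params[prefix + "W2"] + params[prefix + "b2"]
    inner = zp + f if config.ffn_residual else f
    out = inner.layernorm(config.layernorm_eps)
    out = out * params[prefix + "ln2_g"] + params[prefix + "ln2_b"]
    out = out * Tensor(mask[:, :, None])
    return out if batched else out.reshape(n, d)


def gat_layer(
    node_features: Tensor | np.ndarray,
    adjacency: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    prefix: str = "gat1_",
) -> Tensor:
    """One graph attention layer: (N2, k) node features -> (N2, d) embeddings.

    Raw attention logits e_ij = LeakyReLU(a^T [W1 g_i || W1 g_j]) over each
    node's neighborhood plus itself, softmax-normalized, then a ReLU of the
    attention-weighted sum of W2-transformed neighbors.  An isolated node
    attends only to itself (weight exactly 1).
    """
    adj = np.asarray(adjacency, dtype=np.float64)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency diagonal must be zero; the self-term is added here")
    g = node_features if isinstance(node_features, Tensor) else Tensor(node_features)
    n = g.shape[0]
    d = config.embed_dim
    H = g @ params[prefix + "W1"]  # (n, d)
    a = params[prefix + "a"]  # (2d, 1); a^T [x_i || x_j] = a_top.x_i + a_bot.x_j
    a_top = a.take_rows(np.arange(d))
    a_bot = a.take_rows(np.arange(d, 2 * d))
    s_i = H @ a_top  # (n, 1) source term
    s_j = H @ a_bot  # (n, 1) target term
    e = (s_i + s_j.transpose(1, 0)).leaky_relu(config.leaky_slope)  # (n, n)
    neigh = adj + np.eye(n)
    alpha = _masked_softmax(e, neigh)
    out = (alpha @ (g @ params[prefix + "W2"])).relu()
    return out


def align_node_embeddings(
    node_embeddings: Tensor | np.ndarray,
    tokens: CellTokenSequence | np.ndarray,
    pad_id: int,
) -> Tensor:
    """Gather each token position's gene embedding; PAD positions get zeros.

    ``node_embeddings`` rows must be ordered by token id (the graph is
    restricted to the vocabulary first), so token id == node row.
    """
    g = node_embeddings if isinstance(node_embeddings, Tensor) else Tensor(node_embeddings)
    ids = tokens.token_ids if isinstance(tokens, CellTokenSequence) else np.asarray(tokens)
    if np.any((ids < 0) | (ids > pad_id)):
        raise ValueError("token id outside the node-embedding range")
    if pad_id != g.shape[0]:
        raise ValueError(
            f"node embeddings have {g.shape[0]} rows but pad_id is {pad_id}; "
            "restrict the graph to the vocabulary first"
        )
    aug = concat([g, Tensor(np.zeros((1, g.shape[1])))], axis=0)
    return aug.take_rows(ids)


def gated_aggregate(
    T_in: Tensor | np.ndarray,
    G_aligned: Tensor | np.ndarray,
    params: ModelParams,
    prefix: str = "ga1_",
    mask: np.ndarray | None = None,
) -> Tensor:
    """Fuse token-path and graph-path embeddings per position.

    Concatenates the two (..., n, d) inputs to (..., n, 2d) and projects
    through a rectified linear map back to d; outputs are elementwise >= 0.
    """
    t = T_in if isinstance(T_in, Tensor) else Tensor(T_in)
    g = G_aligned if isinstance(G_aligned, Tensor) else Tensor(G_aligned)
    if t.shape != g.shape:
        raise ValueError(f"shape mismatch: token path {t.shape} vs graph path {g.shape}")
    zc = concat([t, g], axis=-1)
    zf = (zc @ params[prefix + "W3"] + params[prefix + "b3"]).relu()
    if mask is not None:
        zf = zf * Tensor(np.asarray(mask, dtype=np.float64)[..., None])
    return zf


def output_head(
    T_final: Tensor | np.ndarray,
    params: ModelParams,
    config: ModelConfig,
) -> Tensor:
    """Flatten -> bottleneck -> 2-way classification probabilities.

    Row-major flatten of the (n_tokens, d) representation (PAD rows enter as
    zeros), linear compression to the bottleneck, then a 2-logit layer mapped
    through an elementwise sigmoid (default) or a softmax.  Index 0 is the
    resistance probability, index 1 the sensitivity probability.
    """
    x = T_final if isinstance(T_final, Tensor) else Tensor(T_final)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("output head input contains non-finite values")
    batched = x.ndim == 3
    if not batched:
        x = x.reshape(1, *x.shape)
    B = x.shape[0]
    flat = x.reshape(B, config.n_tokens * config.embed_dim)
    zs = flat @ params["out_W4"] + params["out_b4"]
    logits = zs @ params["out_W5"] + params["out_b5"]
    if config.output_normalization == "softmax":
        p = logits.softmax(axis=-1)
    else:
        p = logits.sigmoid()
    return p if batched else p.reshape(2)


def cross_entropy(p: Tensor | np.ndarray, y: np.ndarray) -> Tensor:
    """Two-component binary cross-entropy against a one-hot label pair.

    L = -sum_c [ y_c log p_c + (1 - y_c) log(1 - p_c) ], probabilities
    clamped to [1e-7, 1 - 1e-7] before the log.  Accepts a single pair or a
    batch of pairs; batches return the per-cell mean.
    """
    pt = p if isinstance(p, Tensor) else Tensor(p)
    y = np.asarray(y, dtype=np.float64)
    if y.shape != pt.shape:
        raise ValueError("label shape must match probability shape")
    flat = y.reshape(-1, 2)
    if not all(tuple(row) in ((1.0, 0.0), (0.0, 1.0)) for row in flat):
        raise ValueError("labels must be one-hot pairs (1,0) or (0,1)")
    pc = pt.clip(1e-7, 1.0 - 1e-7)
    yt = Tensor(y)
    terms = yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()
    loss = -(terms.sum())
    n_pairs = flat.shape[0]
    return loss / n_pairs


def _apply_dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


def forward(
    tokens: np.ndarray | Sequence[CellTokenSequence],
    graph: KnowledgeGraph,
    params: ModelParams,
    config: ModelConfig,
    vocab: GeneVocabulary,
    ablate_graph: bool = False,
    ablation_mode: str = "identity",
    dropout_rng: np.random.Generator | None = None,
) -> Tensor:
    """Full forward pass on a batch of token sequences -> (B, 2) probabilities.

    ``graph`` must already be restricted to the vocabulary (node order ==
    token-id order).  ``ablate_graph`` selects the reduced model: with
    ``ablation_mode='identity'`` both fusions and graph passes are removed
    (pure encoder stack of the same depth); with ``'zero_graph'`` the graph
    path is kept but fed all-zero node embeddings.
    """
    if isinstance(tokens, np.ndarray):
        token_arr = np.asarray(tokens, dtype=np.int64)
    else:
        token_arr = sequences_to_array(tokens)
    if token_arr.ndim == 1:
        token_arr = token_arr[None, :]
    B, n = token_arr.shape
    if n != config.n_tokens:
        raise ValueError(f"sequences have length {n}, config.n_tokens is {config.n_tokens}")
    if not ablate_graph or ablation_mode == "zero_graph":
        if graph.genes != vocab.symbols:
            raise ValueError("graph must be restricted to the vocabulary (same gene order)")
    mask = (token_arr != vocab.pad_id).astype(np.float64)
    if np.any(mask.sum(axis=1) == 0):
        raise ValueError("batch contains an all-pad cell")

    emb = params["tok_emb"].take_rows(token_arr) + params["pos_emb"].take_rows(
        np.arange(n)
    )
    x = emb * Tensor(mask[:, :, None])

    E = config.encoder_count
    use_graph = not ablate_graph
    zero_graph = ablate_graph and ablation_mode == "zero_graph"

    drop = config.dropout
    rng = dropout_rng

    x = encoder_block(x, mask, params, config, prefix="enc0_")
    if drop > 0 and rng is not None:
        x = _apply_dropout(x, drop, rng)

    g1 = g2 = None
    if use_graph or zero_graph:
        feats = graph.node_features
        if zero_graph:
            feats = np.zeros_like(feats)
        g1 = gat_layer(feats, graph.adjacency, params, config, prefix="gat1_")
        gt1 = align_node_embeddings(g1, token_arr, vocab.pad_id)
        x = gated_aggregate(x, gt1, params, prefix="ga1_", mask=mask)

    for l in range(1, max(E - 1, 1)):
        x = encoder_block(x, mask, params, config, prefix=f"enc{l}_")
        if drop > 0 and rng is not None:
            x = _apply_dropout(x, drop, rng)

    if use_graph or zero_graph:
        g2 = gat_layer(g1, graph.adjacency, params, config, prefix="gat2_")
        gt2 = align_node_embeddings(g2, token_arr, vocab.pad_id)
        x = gated_aggregate(x, gt2, params, prefix="ga2_", mask=mask)

    if E >= 2:
        x = encoder_block(x, mask, params, config, prefix=f"enc{E - 1}_")

    return output_head(x, params, config)


def predict(
    tokens: Sequence[CellTokenSequence],
    graph: KnowledgeGraph,
    params: ModelParams,
    config: ModelConfig,
    vocab: GeneVocabulary,
    threshold: float = 0.5,
    batch_size: int = 64,
    ablate_graph: bool = False,
) -> list[PredictionResult]:
    """Score cells in batches and return per-cell probabilities and calls."""
    results: list[PredictionResult] = []
    for start in range(0, len(tokens), batch_size):
        chunk = list(tokens[start : start + batch_size])
        p = forward(chunk, graph, params, config, vocab, ablate_graph=ablate_graph).data
        for seq, row in zip(chunk, p):
            call = "resistant" if row[0] >= threshold else "sensitive"
            results.append(
                PredictionResult(
                    cell_id=seq.cell_id,
                    p_resistant=float(row[0]),
                    p_sensitive=float(row[1]),
                    call=call,
                )
            )
    return results
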