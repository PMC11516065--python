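"""Independent straight-line NumPy reference implementations used as
oracles by the unit and acceptance tests.  Deliberately written with explicit
loops and no autograd, so they share no code path with the package."""

import numpy as np

from drugformer.model import leaky_relu


def _softmax_rows(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _ln(x, eps):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def ref_encoder(X, mask, params, cfg, prefix):
    """Straight-line single-cell transformer encoder block."""
    g = lambda name: params[prefix + name].data
    n, d = X.shape
    h, dh = cfg.n_heads, cfg.head_dim
    Q, K, V = X @ g("Wq") + g("bq"), X @ g("Wk") + g("bk"), X @ g("Wv") + g("bv")
    Z = np.zeros((n, d))
    for head in range(h):
        sl = slice(head * dh, (head + 1) * dh)
        scores = Q[:, sl] @ K[:, sl].T / cfg.scale + (1 - mask)[None, :] * -1e9
        Z[:, sl] = _softmax_rows(scores) @ V[:, sl]
    Z = Z * mask[:, None]
    Z = Z @ g("Wo") + g("bo")
    Zp = _ln(X + Z, cfg.layernorm_eps) * g("ln1_g") + g("ln1_b")
    F = np.maximum(Zp @ g("W1") + g("b1"), 0) @ g("W2") + g("b2")
    inner = Zp + F if cfg.ffn_residual else F
    out = _ln(inner, cfg.layernorm_eps) * g("ln2_g") + g("ln2_b")
    return out * mask[:, None]


def ref_gat(features, adj, params, cfg, prefix):
    """Brute-force per-edge evaluation of the graph attention layer."""
    W1 = params[prefix + "W1"].data
    W2 = params[prefix + "W2"].data
    a = params[prefix + "a"].data[:, 0]
    n = features.shape[0]
    d = cfg.embed_dim
    H = features @ W1
    out = np.zeros((n, d))
    alphas = {}
    for i in range(n):
        nbrs = [i] + [j for j in range(n) if adj[i, j]]
        e = np.array(
            [leaky_relu(float(a[:d] @ H[i] + a[d:] @ H[j]), cfg.leaky_slope) for j in nbrs]
        )
        alpha = np.exp(e - e.max())
        alpha = alpha / alpha.sum()
        alphas[i] = dict(zip(nbrs, alpha))
        agg = sum(alpha[t] * (features[j] @ W2) for t, j in enumerate(nbrs))
        out[i] = np.maximum(agg, 0)
    return out, alphas


def ref_output_head(X, params, cfg):
    flat = X.reshape(1, -1)
    zs = flat @ params["out_W4"].data + params["out_b4"].data
    logits = zs @ params["out_W5"].data + params["out_b5"].data
    if cfg.output_normalization == "softmax":
        return _softmax_rows(logits)[0]
    return (1.0 / (1.0 + np.exp(-logits)))[0]


def all_pairs_auc(labels, scores):
    """Brute-force AUC: mean over positive-negative pairs with \u00bd tie credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
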