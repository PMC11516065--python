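"""Training loop, k-fold cross-validation, metrics, ablation, baselines, and
the intra-tumoral heterogeneity (ITH) entropy statistic.

The evaluation protocol is five-fold cross-validation: cells are randomly
partitioned into five disjoint, near-equal folds; each fold serves once as
the held-out test set while the remaining folds train the model.  Metrics
(accuracy, F1, precision, recall, AUC; "resistant" is the positive class)
are reported per fold and as unweighted fold means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.svm import SVC

from .autograd import Adam
from .graph import KnowledgeGraph, restrict_to_vocabulary
from .model import ModelConfig, ModelParams, cross_entropy, forward
from .synthetic import SyntheticDataset
from .tokenization import build_vocabulary, sequences_to_array, serialize_matrix

__all__ = [
    "TrainConfig",
    "EvalReport",
    "make_folds",
    "train_fold",
    "compute_metrics",
    "cross_validate",
    "run_ablation",
    "baseline_harness",
    "shannon_ith",
]

AUC_UNDEFINED = float("nan")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    epochs: int = 5
    folds: int = 5
    learning_rate: float = 3e-3
    seed: int = 0
    ablate_graph: bool = False
    ablation_mode: str = "identity"

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


@dataclass
class EvalReport:
    """Per-fold and mean metrics plus fold assignment and loss traces."""

    per_fold: list[dict]
    mean: dict
    fold_assignment: np.ndarray
    loss_traces: list[list[float]]
    scores: np.ndarray | None = None  # out-of-fold resistance probabilities


def make_folds(n_cells: int, k: int, seed: int) -> np.ndarray:
    """Seeded random partition into k folds whose sizes differ by <= 1.

    Returns an array of fold ids (0..k-1), one per cell.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_cells:
        raise ValueError(f"cannot split {n_cells} cells into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    assignment = np.empty(n_cells, dtype=np.int64)
    sizes = np.full(k, n_cells // k)
    sizes[: n_cells % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignment[order[start : start + size]] = fold
        start += size
    return assignment


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: ties between a positive and a negative get ½ credit."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return AUC_UNDEFINED
    ranks = rankdata(scores)  # average ranks implement the ½ tie credit
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Accuracy, F1, precision, recall and rank-based AUC.

    "resistant" (label 1) is the positive class.  AUC is reported as NaN
    when only one class is present; the thresholded metrics are still
    computed.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    preds = (scores >= threshold).astype(np.int64)
    return {
        "accuracy": float(accuracy_score(labels, preds)),
        "precision": float(precision_score(labels, preds, zero_division=0)),
        "recall": float(recall_score(labels, preds, zero_division=0)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
        "auc": _rank_auc(labels, scores),
    }


def _mean_metrics(per_fold: list[dict]) -> dict:
    keys = per_fold[0].keys()
    out = {}
    for key in keys:
        vals = [m[key] for m in per_fold if not np.isnan(m[key])]
        out[key] = float(np.mean(vals)) if vals else AUC_UNDEFINED
    return out


@dataclass
class _Prepared:
    tokens: np.ndarray  # (n_cells, n_tokens)
    labels: np.ndarray
    graph: KnowledgeGraph
    vocab: "object"


def prepare_dataset(
    dataset: SyntheticDataset,
    graph: KnowledgeGraph,
    model_config: ModelConfig,
) -> _Prepared:
    """Tokenize every cell and restrict the graph to the expression vocabulary."""
    vocab = build_vocabulary(dataset.gene_symbols)
    # serialize_matrix expects columns in token-id (sorted-symbol) order
    col_order = np.argsort([s.upper() for s in dataset.gene_symbols], kind="stable")
    sequences = serialize_matrix(
        dataset.expression[:, col_order], vocab, model_config.n_tokens,
        cell_ids=dataset.cell_ids,
    )
    tokens = sequences_to_array(sequences)
    restricted = restrict_to_vocabulary(graph, vocab)
    return _Prepared(tokens=tokens, labels=dataset.labels, graph=restricted, vocab=vocab)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((labels.shape[0], 2))
    y[labels == 1, 0] = 1.0  # (1, 0) = resistant
    y[labels == 0, 1] = 1.0  # (0, 1) = sensitive
    return y


def _train_on(
    prep: _Prepared,
    train_idx: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int,
) -> tuple[ModelParams, list[float]]:
    if train_idx.size == 0:
        raise ValueError("empty training split")
    params = ModelParams.init(
        model_config,
        vocab_size=len(prep.vocab),
        feature_dim=prep.graph.node_features.shape[1],
        seed=seed,
    )
    opt = Adam(params.values(), lr=train_config.learning_rate)
    rng = np.random.default_rng(seed + 1)
    drop_rng = np.random.default_rng(seed + 2) if model_config.dropout > 0 else None
    trace: list[float] = []
    y_all = _one_hot(prep.labels)
    for _epoch in range(train_config.epochs):
        order = rng.permutation(train_idx)
        epoch_losses: list[float] = []
        epoch_sizes: list[int] = []
        for start in range(0, order.size, train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            if train_config.learning_rate == 0:
                # null update: evaluate loss only, parameters stay fixed
                p = forward(
                    prep.tokens[batch], prep.graph, params, model_config, prep.vocab,
                    ablate_graph=train_config.ablate_graph,
                    ablation_mode=train_config.ablation_mode,
                )
                loss = cross_entropy(p, y_all[batch])
                epoch_losses.append(float(loss.data))
                epoch_sizes.append(batch.size)
                continue
            opt.zero_grad()
            p = forward(
                prep.tokens[batch], prep.graph, params, model_config, prep.vocab,
                ablate_graph=train_config.ablate_graph,
                ablation_mode=train_config.ablation_mode,
                dropout_rng=drop_rng,
            )
            loss = cross_entropy(p, y_all[batch])
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            epoch_sizes.append(batch.size)
        # cell-weighted epoch mean: invariant to how the shuffle cuts batches
        trace.append(
            float(np.average(epoch_losses, weights=epoch_sizes))
            if epoch_losses else float("nan")
        )
    return params, trace


def _score_cells(
    prep: _Prepared,
    idx: np.ndarray,
    params: ModelParams,
    model_config: ModelConfig,
    train_config: TrainConfig,
    batch_size: int = 128,
) -> np.ndarray:
    out = np.empty(idx.size)
    for start in range(0, idx.size, batch_size):
        chunk = idx[start : start + batch_size]
        p = forward(
            prep.tokens[chunk], prep.graph, params, model_config, prep.vocab,
            ablate_graph=train_config.ablate_graph,
            ablation_mode=train_config.ablation_mode,
        )
        out[start : start + chunk.size] = p.data[:, 0]
    return out


def train_fold(
    dataset: SyntheticDataset,
    graph: KnowledgeGraph,
    fold_assignment: np.ndarray,
    fold: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[ModelParams, list[float]]:
    """Train on all folds except ``fold``; returns params and the per-epoch
    mean training-loss trace.  Deterministic given the seed."""
    prep = prepare_dataset(dataset, graph, model_config)
    train_idx = np.nonzero(fold_assignment != fold)[0]
    return _train_on(prep, train_idx, model_config, train_config, seed=train_config.seed)


def cross_validate(
    dataset: SyntheticDataset,
    graph: KnowledgeGraph,
    model_config: ModelConfig,
    train_config: TrainConfig,
    verbose: bool = False,
) -> EvalReport:
    """k-fold cross-validation; per-fold metrics and their unweighted mean."""
    prep = prepare_dataset(dataset, graph, model_config)
    folds = make_folds(dataset.n_cells, train_config.folds, train_config.seed)
    per_fold: list[dict] = []
    traces: list[list[float]] = []
    oof = np.full(dataset.n_cells, np.nan)
    for fold in range(train_config.folds):
        train_idx = np.nonzero(folds != fold)[0]
        test_idx = np.nonzero(folds == fold)[0]
        params, trace = _train_on(
            prep, train_idx, model_config, train_config, seed=train_config.seed + fold
        )
        scores = _score_cells(prep, test_idx, params, model_config, train_config)
        oof[test_idx] = scores
        metrics = compute_metrics(prep.labels[test_idx], scores)
        per_fold.append(metrics)
        traces.append(trace)
        if verbose:
            print(f"fold {fold}: " + ", ".join(f"{k}={v:.3f}" for k, v in metrics.items()))
    return EvalReport(
        per_fold=per_fold,
        mean=_mean_metrics(per_fold),
        fold_assignment=folds,
        loss_traces=traces,
        scores=oof,
    )


def run_ablation(
    dataset: SyntheticDataset,
    graph: KnowledgeGraph,
    model_config: ModelConfig,
    train_config: TrainConfig,
    ablation_mode: str = "identity",
    verbose: bool = False,
) -> tuple[EvalReport, EvalReport]:
    """Paired full-vs-reduced comparison with identical folds and seeds.

    The reduced model removes both graph-attention passes and both fusion
    steps, leaving a pure transformer encoder stack of the same depth
    (``ablation_mode='zero_graph'`` instead keeps the graph path but feeds it
    zeroed node embeddings).
    """
    full_cfg = replace(train_config, ablate_graph=False)
    reduced_cfg = replace(train_config, ablate_graph=True, ablation_mode=ablation_mode)
    full = cross_validate(dataset, graph, model_config, full_cfg, verbose=verbose)
    reduced = cross_validate(dataset, graph, model_config, reduced_cfg, verbose=verbose)
    return full, reduced


def baseline_harness(
    dataset: SyntheticDataset,
    fold_assignment: np.ndarray,
    seed: int = 0,
) -> dict[str, dict]:
    """RF / SVM / LR on the flat expression matrix with the given folds.

    A thin adapter over scikit-learn classifiers for report parity; each
    model is trained per fold on the remaining folds and scored on the
    held-out fold, mirroring the cross-validation protocol.
    """
    X = dataset.expression
    y = dataset.labels
    k = int(fold_assignment.max()) + 1
    makers = {
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "SVM": lambda: SVC(random_state=seed),
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=seed),
    }
    out: dict[str, dict] = {}
    for name, make in makers.items():
        per_fold = []
        for fold in range(k):
            train = fold_assignment != fold
            test = ~train
            clf = make().fit(X[train], y[train])
            if hasattr(clf, "predict_proba"):
                scores = clf.predict_proba(X[test])[:, 1]
            else:
                raw = clf.decision_function(X[test])
                scores = 1.0 / (1.0 + np.exp(-raw))
            per_fold.append(compute_metrics(y[test], scores))
        out[name] = {"per_fold": per_fold, "mean": _mean_metrics(per_fold)}
    return out


def shannon_ith(proportions) -> float:
    """Shannon entropy (natural log) of cell-state proportions: -sum p ln p.

    Zeros contribute nothing (0 ln 0 := 0); proportions must be nonnegative
    and sum to 1 within 1e-6.
    """
    p = np.asarray(proportions, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {p.sum():.8f}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() + 0.0)
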