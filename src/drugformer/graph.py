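"""Gene-level knowledge graph built from dosage-sensitivity score similarity.

Each gene carries two probabilities — pHaplo (haploinsufficiency: intolerance
to deletion) and pTriplo (triplosensitivity: intolerance to duplication).
Two genes are connected in the knowledge graph when their (pHaplo, pTriplo)
pairs are similar, measured by Euclidean distance against a threshold tau.
Node features default to the score pair itself but may carry extra numeric
columns from the score table.

Self-edges are never stored: the graph attention layer adds each node's own
contribution once via the neighborhood-plus-self softmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .tokenization import GeneVocabulary

__all__ = [
    "GeneScoreTable",
    "KnowledgeGraph",
    "build_graph",
    "restrict_to_vocabulary",
    "graph_stats",
]

DEFAULT_TAU = 0.05


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene dosage-sensitivity scores plus optional extra feature columns."""

    symbols: list[str]
    phaplo: np.ndarray  # (n,) in [0, 1]
    ptriplo: np.ndarray  # (n,) in [0, 1]
    extra_features: np.ndarray | None = None  # (n, m) or None

    def __post_init__(self):
        object.__setattr__(self, "phaplo", np.asarray(self.phaplo, dtype=np.float64))
        object.__setattr__(self, "ptriplo", np.asarray(self.ptriplo, dtype=np.float64))
        n = len(self.symbols)
        if self.phaplo.shape != (n,) or self.ptriplo.shape != (n,):
            raise ValueError("score arrays must match the number of symbols")
        if len(set(self.symbols)) != n:
            raise ValueError("duplicate gene symbols in score table")
        for name, arr in (("pHaplo", self.phaplo), ("pTriplo", self.ptriplo)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def score_pairs(self) -> np.ndarray:
        return np.column_stack([self.phaplo, self.ptriplo])

    def feature_matrix(self, use_extra: bool = False) -> np.ndarray:
        """Node features: the (pHaplo, pTriplo) pair, optionally with extras."""
        base = self.score_pairs
        if use_extra and self.extra_features is not None:
            return np.column_stack([base, self.extra_features])
        return base

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"gene": self.symbols, "pHaplo": self.phaplo, "pTriplo": self.ptriplo}
        )
        if self.extra_features is not None:
            for j in range(self.extra_features.shape[1]):
                df[f"feature_{j + 1}"] = self.extra_features[:, j]
        return df


@dataclass(frozen=True)
class KnowledgeGraph:
    """Symmetric gene graph with per-node feature vectors.

    ``adjacency`` is a dense 0/1 matrix with zero diagonal;
    ``node_features`` has one length-k row per gene, in ``genes`` order.
    """

    genes: list[str]
    adjacency: np.ndarray  # (n, n) binary, symmetric, zero diagonal
    node_features: np.ndarray  # (n, k)

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=np.float64)
        feats = np.asarray(self.node_features, dtype=np.float64)
        n = len(self.genes)
        if adj.shape != (n, n):
            raise ValueError("adjacency shape does not match gene count")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have a zero diagonal (no stored self-edges)")
        if feats.ndim != 2 or feats.shape[0] != n:
            raise ValueError("node_features must have one row per gene")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "node_features", feats)

    @property
    def n_nodes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edge_list(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.genes[a], self.genes[b]) for a, b in zip(i, j)]


def build_graph(
    scores: GeneScoreTable,
    tau: float = DEFAULT_TAU,
    max_degree: int | None = None,
    use_extra_features: bool = False,
) -> KnowledgeGraph:
    """Connect genes whose (pHaplo, pTriplo) pairs lie within distance tau.

    With ``max_degree`` set, each node keeps only its ``max_degree`` nearest
    neighbors (by score distance) and the edge set is re-symmetrized by
    union.  Larger tau gives a superset of edges (monotone thresholding).
    """
    if len(scores) < 2:
        raise ValueError("score table must contain at least 2 genes")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    pairs = scores.score_pairs
    dist = cdist(pairs, pairs)
    adj = (dist <= tau).astype(np.float64)
    np.fill_diagonal(adj, 0.0)
    if max_degree is not None:
        if max_degree < 0:
            raise ValueError("max_degree must be nonnegative")
        kept = np.zeros_like(adj)
        for i in range(len(scores)):
            nbrs = np.nonzero(adj[i])[0]
            if nbrs.size > max_degree:
                nearest = nbrs[np.argsort(dist[i, nbrs], kind="stable")[:max_degree]]
            else:
                nearest = nbrs
            kept[i, nearest] = 1.0
        adj = np.maximum(kept, kept.T)  # union re-symmetrization
    return KnowledgeGraph(
        genes=list(scores.symbols),
        adjacency=adj,
        node_features=scores.feature_matrix(use_extra=use_extra_features),
    )


def restrict_to_vocabulary(graph: KnowledgeGraph, vocab: GeneVocabulary) -> KnowledgeGraph:
    """Reconcile graph genes with an expression vocabulary.

    The result's node set equals the vocabulary (in token-id order): genes in
    both keep their features and induced edges; vocabulary genes absent from
    the graph become isolated nodes with zero feature vectors, so the graph
    attention layer contributes only their self-term.
    """
    vocab_symbols = vocab.symbols
    if not vocab_symbols:
        raise ValueError("restriction produced a graph with zero genes")
    k = graph.node_features.shape[1]
    index = {g: i for i, g in enumerate(graph.genes)}
    n = len(vocab_symbols)
    adj = np.zeros((n, n), dtype=np.float64)
    feats = np.zeros((n, k), dtype=np.float64)
    present = [(i, index[g]) for i, g in enumerate(vocab_symbols) if g in index]
    if present:
        new_idx = np.array([p[0] for p in present])
        old_idx = np.array([p[1] for p in present])
        adj[np.ix_(new_idx, new_idx)] = graph.adjacency[np.ix_(old_idx, old_idx)]
        feats[new_idx] = graph.node_features[old_idx]
    return KnowledgeGraph(genes=vocab_symbols, adjacency=adj, node_features=feats)


def graph_stats(graph: KnowledgeGraph) -> dict:
    """Exact node/edge counts, degree distribution, and component count."""
    degrees = graph.adjacency.sum(axis=1).astype(int)
    n_components, _ = connected_components(
        csr_matrix(graph.adjacency), directed=False
    )
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "degrees": degrees,
        "n_components": int(n_components),
    }
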