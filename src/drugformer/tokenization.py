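"""Rank serialization of single-cell expression profiles into gene tokens.

Each cell is represented as an ordered sequence of its most highly expressed
genes: the gene with the highest (post-normalization) value comes first, and
so on, down to a fixed sequence length ``n_tokens``.  Genes with zero
expression are never tokenized; if a cell expresses fewer than ``n_tokens``
genes, the tail of the sequence is filled with a dedicated PAD token that the
model masks out of attention.

Ties in expression are broken by ascending token id so that serialization is
deterministic across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GeneVocabulary",
    "CellTokenSequence",
    "build_vocabulary",
    "serialize_cell",
    "serialize_matrix",
]

DEFAULT_N_TOKENS = 2048


@dataclass(frozen=True)
class GeneVocabulary:
    """Bidirectional gene-symbol <-> token-id map with a reserved PAD id.

    Ids are assigned ``0..n-1`` in sorted-symbol order; ``pad_id`` is ``n``
    and is never mapped to a gene symbol.
    """

    symbol_to_id: dict[str, int]
    id_to_symbol: dict[int, str]
    pad_id: int

    def __len__(self) -> int:
        return len(self.symbol_to_id)

    @property
    def symbols(self) -> list[str]:
        return [self.id_to_symbol[i] for i in range(len(self.symbol_to_id))]


@dataclass(frozen=True)
class CellTokenSequence:
    """One cell's serialized token sequence of fixed length.

    ``n_real`` counts the non-pad tokens; pad tokens occupy only the tail.
    """

    cell_id: str
    token_ids: np.ndarray  # shape (n_tokens,), int
    n_real: int

    def __post_init__(self):
        object.__setattr__(self, "token_ids", np.asarray(self.token_ids, dtype=np.int64))


def build_vocabulary(gene_symbols: Sequence[str]) -> GeneVocabulary:
    """Build a vocabulary from gene symbols (uppercased, sorted, unique).

    Raises ``ValueError`` naming the duplicates if two symbols collide after
    uppercasing.
    """
    if len(gene_symbols) == 0:
        raise ValueError("gene symbol list is empty")
    upper = [str(s).upper() for s in gene_symbols]
    seen: dict[str, int] = {}
    dups: list[str] = []
    for s in upper:
        seen[s] = seen.get(s, 0) + 1
        if seen[s] == 2:
            dups.append(s)
    if dups:
        raise ValueError(f"duplicate gene symbols after uppercasing: {sorted(dups)}")
    ordered = sorted(upper)
    symbol_to_id = {s: i for i, s in enumerate(ordered)}
    id_to_symbol = {i: s for s, i in symbol_to_id.items()}
    return GeneVocabulary(symbol_to_id, id_to_symbol, pad_id=len(ordered))


def serialize_cell(
    expression: Mapping[str, float] | np.ndarray,
    vocab: GeneVocabulary,
    n_tokens: int = DEFAULT_N_TOKENS,
    cell_id: str = "",
) -> CellTokenSequence:
    """Serialize one cell into its top-``n_tokens`` expressed gene tokens.

    ``expression`` is either a mapping ``symbol -> value`` or a dense vector
    indexed by token id.  Tokens are ordered by decreasing expression, ties
    broken by ascending token id; zero-expression genes are excluded and the
    tail is padded with ``vocab.pad_id``.
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    n_genes = len(vocab)
    values = np.zeros(n_genes, dtype=np.float64)
    if isinstance(expression, Mapping):
        for sym, val in expression.items():
            key = str(sym).upper()
            if key not in vocab.symbol_to_id:
                raise ValueError(f"gene {sym!r} absent from vocabulary")
            values[vocab.symbol_to_id[key]] = val
    else:
        vec = np.asarray(expression, dtype=np.float64)
        if vec.shape != (n_genes,):
            raise ValueError(
                f"expression vector length {vec.shape} does not match vocabulary size {n_genes}"
            )
        values = vec
    if np.any(values < 0):
        raise ValueError("expression values must be nonnegative")
    # stable sort on ascending id, then stable sort on descending value:
    # equal values keep ascending-id order.
    order = np.argsort(-values, kind="stable")
    expressed = order[values[order] > 0]
    n_real = int(min(n_tokens, expressed.size))
    token_ids = np.full(n_tokens, vocab.pad_id, dtype=np.int64)
    token_ids[:n_real] = expressed[:n_real]
    return CellTokenSequence(cell_id=cell_id, token_ids=token_ids, n_real=n_real)


def serialize_matrix(
    expression: np.ndarray,
    vocab: GeneVocabulary,
    n_tokens: int = DEFAULT_N_TOKENS,
    cell_ids: Sequence[str] | None = None,
) -> list[CellTokenSequence]:
    """Serialize every row (cell) of a cells x genes matrix, preserving order.

    Columns must be ordered by token id (i.e. sorted gene symbol).
    """
    matrix = np.asarray(expression, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("expression must be a 2-D cells x genes matrix")
    if matrix.shape[0] and matrix.shape[1] != len(vocab):
        raise ValueError(
            f"matrix has {matrix.shape[1]} genes but vocabulary has {len(vocab)}"
        )
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(matrix.shape[0])]
    return [
        serialize_cell(matrix[i], vocab, n_tokens, cell_id=str(cell_ids[i]))
        for i in range(matrix.shape[0])
    ]


def sequences_to_array(sequences: Sequence[CellTokenSequence]) -> np.ndarray:
    """Stack token sequences into an (n_cells, n_tokens) int array."""
    if not sequences:
        return np.zeros((0, 0), dtype=np.int64)
    return np.stack([s.token_ids for s in sequences])
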