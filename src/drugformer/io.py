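"""Readers and writers for the external formats, plus run manifests and
model checkpoints.

Conventions: Matrix Market files store genes as rows and cells as columns
(the community convention for 10x-style exports) and are transposed to
cells-as-rows in memory; TSVs are tab-delimited UTF-8 with headers; gene
symbols are uppercased on ingest everywhere so expression, scores, and graph
join consistently.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .graph import GeneScoreTable, KnowledgeGraph
from .model import ModelConfig, ModelParams
from .tokenization import GeneVocabulary, build_vocabulary

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_scores",
    "write_scores",
    "write_graph",
    "save_checkpoint",
    "load_checkpoint",
    "write_manifest",
]


class FormatError(ValueError):
    """A file failed format validation."""


def read_expression(path: str | Path, fmt: str | None = None):
    """Read a cells x genes matrix from MTX (+ genes.tsv / barcodes.tsv
    companions in the same directory) or a dense CSV.

    Returns ``(matrix, cell_ids, gene_symbols)`` with genes uppercased and
    cells as rows.  CSV layout: first column = barcode, header = genes.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
        genes_path = path.parent / "genes.tsv"
        barcodes_path = path.parent / "barcodes.tsv"
        genes = [line.split("\t")[0].strip().upper() for line in genes_path.read_text().splitlines() if line.strip()]
        barcodes = [line.strip() for line in barcodes_path.read_text().splitlines() if line.strip()]
        if mat.shape[0] != len(genes):
            raise FormatError(
                f"matrix has {mat.shape[0]} gene rows but genes.tsv lists {len(genes)}"
            )
        if mat.shape[1] != len(barcodes):
            raise FormatError(
                f"matrix has {mat.shape[1]} cell columns but barcodes.tsv lists {len(barcodes)}"
            )
        matrix = mat.T  # genes-as-rows on disk -> cells-as-rows in memory
        cell_ids, gene_symbols = barcodes, genes
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        matrix = df.to_numpy(dtype=np.float64)
        cell_ids = [str(i) for i in df.index]
        gene_symbols = [str(c).upper() for c in df.columns]
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    if np.any(matrix < 0):
        raise FormatError("expression matrix contains negative values")
    return matrix, cell_ids, gene_symbols


def write_expression(
    out_dir: str | Path,
    matrix: np.ndarray,
    cell_ids: list[str],
    gene_symbols: list[str],
    fmt: str = "mtx",
) -> Path:
    """Write a cells x genes matrix as MTX (+ companions) or dense CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix = np.asarray(matrix, dtype=np.float64)
    if fmt == "mtx":
        target = out_dir / "matrix.mtx"
        sparse = scipy.sparse.coo_matrix(matrix.T)  # genes as rows on disk
        scipy.io.mmwrite(target, sparse)
        (out_dir / "genes.tsv").write_text("".join(f"{g}\n" for g in gene_symbols))
        (out_dir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in cell_ids))
        return target
    if fmt == "csv":
        target = out_dir / "expression.csv"
        pd.DataFrame(matrix, index=cell_ids, columns=gene_symbols).to_csv(target)
        return target
    raise ValueError(f"unknown expression format {fmt!r}")


_LABEL_MAP = {"resistant": 1, "sensitive": 0}


def read_labels(path: str | Path, cell_ids: list[str] | None = None) -> np.ndarray:
    """Read a 2-column TSV (barcode, resistant/sensitive) into 0/1 labels.

    With ``cell_ids`` given, labels are re-ordered to match; missing or
    unknown entries raise a ``FormatError`` naming the offenders.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label file must have two columns: barcode, label")
    barcodes = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.lower().tolist()
    bad = sorted({v for v in raw if v not in _LABEL_MAP})
    if bad:
        raise FormatError(f"unknown label values {bad}; expected resistant/sensitive")
    mapping = {b: _LABEL_MAP[v] for b, v in zip(barcodes, raw)}
    if cell_ids is None:
        return np.array([_LABEL_MAP[v] for v in raw], dtype=np.int64)
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise FormatError(f"barcodes missing from label file: {missing[:10]}")
    return np.array([mapping[c] for c in cell_ids], dtype=np.int64)


def write_labels(path: str | Path, cell_ids: list[str], labels: np.ndarray) -> None:
    inv = {1: "resistant", 0: "sensitive"}
    with open(path, "w") as fh:
        fh.write("barcode\tlabel\n")
        for cid, lab in zip(cell_ids, labels):
            fh.write(f"{cid}\t{inv[int(lab)]}\n")


def read_scores(path: str | Path) -> GeneScoreTable:
    """Read a gene score TSV (gene, pHaplo, pTriplo, extra numeric columns).

    Probabilities are validated to [0, 1]; violations raise a ``FormatError``
    naming the 1-based data row.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError("score file needs at least gene, pHaplo, pTriplo columns")
    symbols = df.iloc[:, 0].astype(str).str.upper().tolist()
    ph = df.iloc[:, 1].to_numpy(dtype=np.float64)
    pt = df.iloc[:, 2].to_numpy(dtype=np.float64)
    for name, arr in (("pHaplo", ph), ("pTriplo", pt)):
        bad = np.nonzero((arr < 0) | (arr > 1))[0]
        if bad.size:
            raise FormatError(f"{name} out of [0,1] at row {bad[0] + 1}")
    extra = None
    if df.shape[1] > 3:
        extra = df.iloc[:, 3:].to_numpy(dtype=np.float64)
    return GeneScoreTable(symbols=symbols, phaplo=ph, ptriplo=pt, extra_features=extra)


def write_scores(path: str | Path, scores: GeneScoreTable) -> None:
    scores.to_frame().to_csv(path, sep="\t", index=False)


def write_graph(out_dir: str | Path, graph: KnowledgeGraph) -> None:
    """Write edge-list and node-feature TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "edges.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in graph.edge_list():
            fh.write(f"{a}\t{b}\n")
    k = graph.node_features.shape[1]
    with open(out_dir / "node_features.tsv", "w") as fh:
        fh.write("gene\t" + "\t".join(f"feature_{j + 1}" for j in range(k)) + "\n")
        for gene, row in zip(graph.genes, graph.node_features):
            fh.write(gene + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _graph_fingerprint(graph: KnowledgeGraph) -> str:
    h = hashlib.sha256()
    h.update("\n".join(graph.genes).encode())
    h.update(np.ascontiguousarray(graph.adjacency).tobytes())
    h.update(np.ascontiguousarray(graph.node_features).tobytes())
    return h.hexdigest()[:16]


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    config: ModelConfig,
    vocab: GeneVocabulary,
    graph: KnowledgeGraph,
) -> None:
    """Save config + parameters + vocabulary + a graph fingerprint (.npz)."""
    meta = {
        "config": {k: getattr(config, k) for k in (
            "embed_dim", "n_heads", "n_tokens", "ffn_hidden", "encoder_count",
            "bottleneck_dim", "leaky_slope", "attention_scale", "layernorm_eps",
            "dropout", "output_normalization", "ffn_residual",
        )},
        "vocabulary": vocab.symbols,
        "graph_fingerprint": _graph_fingerprint(graph),
    }
    arrays = {f"param::{k}": v for k, v in params.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns ``(params, config, vocab, fingerprint)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k.removeprefix("param::"): data[k] for k in data.files if k.startswith("param::")}
    config = ModelConfig(**meta["config"])
    vocab = build_vocabulary(meta["vocabulary"])
    params = ModelParams.init(
        config,
        vocab_size=len(vocab),
        feature_dim=state["gat1_W1"].shape[0],
        seed=0,
    )
    params.load_state_dict(state)
    return params, config, vocab, meta["graph_fingerprint"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, inputs: list[str | Path]) -> Path:
    """Write a reproducibility manifest: config, seed, versions, input digests."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
    }
    target = out_dir / "manifest.json"
    target.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return target
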