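"""Serialize cells into ranked gene-token sequences.

A cell's token sequence lists its most highly expressed genes in decreasing
order (ties broken by ascending token id); unexpressed genes are never
tokenized and short cells are padded with a dedicated PAD token that the
model masks out of attention.
"""

import numpy as np

import drugformer as df

vocab = df.build_vocabulary(["ACTB", "COX8A", "FEN1", "GAPDH", "RBX1"])
print(f"vocabulary: {vocab.symbol_to_id}, PAD id = {vocab.pad_id}")

cell = {"ACTB": 40.0, "GAPDH": 35.0, "COX8A": 7.0, "FEN1": 0.0, "RBX1": 7.0}
seq = df.serialize_cell(cell, vocab, n_tokens=5, cell_id="cell_0")
symbols = [vocab.id_to_symbol.get(t, "<PAD>") for t in seq.token_ids]
print(f"expression: {cell}")
print(f"tokens:     {symbols}  (n_real = {seq.n_real})")
print("-> highest expression first; the COX8A/RBX1 tie resolves by token id;")
print("   FEN1 has zero expression, so the tail is padded")

rng = np.random.default_rng(5)
matrix = np.round(rng.random((3, 5)) * 10)
for s in df.serialize_matrix(matrix, vocab, n_tokens=4, cell_ids=["a", "b", "c"]):
    print(s.cell_id, [vocab.id_to_symbol.get(t, "<PAD>") for t in s.token_ids])
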