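"""Model-layer correctness against independent straight-line reimplementations
and brute-force per-edge oracles, plus the wiring/normalization invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drugformer as df
from drugformer.autograd import Tensor
from drugformer.model import (
    align_node_embeddings,
    attention_head,
    cross_entropy,
    encoder_block,
    forward,
    gat_layer,
    gated_aggregate,
    leaky_relu,
    output_head,
)
from drugformer.tokenization import sequences_to_array
from drugformer.training import prepare_dataset

from oracles import ref_encoder, ref_gat, ref_output_head, _ln, _softmax_rows

def make_params(cfg, vocab_size=10, feature_dim=2, seed=0):
    return df.ModelParams.init(cfg, vocab_size=vocab_size, feature_dim=feature_dim, seed=seed)


# ---------------------------------------------------------------------------
# attention / encoder
# ---------------------------------------------------------------------------


class TestAttentionHead:
    def _weights(self, rng, dh):
        mk = lambda shape: Tensor(rng.standard_normal(shape) * 0.5)
        return dict(
            Wq=mk((dh, dh)), bq=mk((dh,)), Wk=mk((dh, dh)), bk=mk((dh,)),
            Wv=mk((dh, dh)), bv=mk((dh,)),
        )

    def test_single_token_outputs_its_value_projection(self, rng):
        w = self._weights(rng, 4)
        x = rng.standard_normal((1, 4))
        out = attention_head(x, np.ones(1), scale=1.0, **w)
        expected = x @ w["Wv"].data + w["bv"].data
        assert np.allclose(out.data, expected)

    def test_identical_tokens_split_weight_evenly(self, rng):
        w = self._weights(rng, 4)
        row = rng.standard_normal(4)
        x = np.stack([row, row])
        out = attention_head(x, np.ones(2), scale=1.0, **w)
        v = x @ w["Wv"].data + w["bv"].data
        assert np.allclose(out.data, np.tile(0.5 * (v[0] + v[1]), (2, 1)))

    def test_three_token_hand_formula(self):
        """Fixed small integer projections, C = 1: matches the direct formula."""
        dh = 2
        I = np.eye(dh)
        w = dict(Wq=Tensor(I), bq=Tensor(np.zeros(dh)), Wk=Tensor(I),
                 bk=Tensor(np.zeros(dh)), Wv=Tensor(2 * I), bv=Tensor(np.zeros(dh)))
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = attention_head(x, np.ones(3), scale=1.0, **w)
        scores = x @ x.T
        attn = _softmax_rows(scores)
        assert np.allclose(out.data, attn @ (2 * x))

    def test_pad_positions_get_zero_weight_and_output(self, rng):
        w = self._weights(rng, 3)
        x = rng.standard_normal((4, 3))
        mask = np.array([1.0, 1.0, 0.0, 0.0])
        out = attention_head(x, mask, scale=1.0, **w)
        assert np.all(out.data[2:] == 0)
        x2 = x.copy()
        x2[2:] = 99.0  # masked content must not influence real positions
        out2 = attention_head(x2, mask, scale=1.0, **w)
        assert np.allclose(out.data[:2], out2.data[:2])

    def test_all_pad_rejected(self, rng):
        w = self._weights(rng, 3)
        with pytest.raises(ValueError):
            attention_head(rng.standard_normal((2, 3)), np.zeros(2), scale=1.0, **w)


class TestEncoderBlock:
    def test_layernorm_closed_form(self):
        out = Tensor(np.array([[1.0, 2.0, 3.0]])).layernorm(1e-12)
        assert np.allclose(out.data, [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_zero_ffn_reduces_to_layernorm_of_attention_sublayer(self, rng):
        cfg = df.ModelConfig(embed_dim=8, n_heads=2, n_tokens=4, encoder_count=1, ffn_hidden=16)
        p = make_params(cfg, seed=1)
        for name in ("W1", "b1", "W2", "b2"):
            p["enc0_" + name].data[:] = 0.0
        x = rng.standard_normal((4, 8))
        mask = np.ones(4)
        out = encoder_block(x, mask, p, cfg, prefix="enc0_")
        # with zero FFN the residual path carries Z' alone into the second norm
        ref = ref_encoder(x, mask, p, cfg, "enc0_")
        assert np.allclose(out.data, ref)

    @pytest.mark.parametrize("residual", [True, False])
    def test_matches_straight_line_reimplementation(self, rng, residual):
        cfg = df.ModelConfig(embed_dim=8, n_heads=2, n_tokens=4, encoder_count=1,
                             ffn_hidden=16, ffn_residual=residual)
        p = make_params(cfg, seed=2)
        x = rng.standard_normal((4, 8))
        mask = np.array([1.0, 1.0, 1.0, 0.0])
        out = encoder_block(x * mask[:, None], mask, p, cfg, prefix="enc0_")
        ref = ref_encoder(x * mask[:, None], mask, p, cfg, "enc0_")
        assert np.allclose(out.data, ref, atol=1e-10)

    def test_non_finite_input_rejected(self, rng):
        cfg = df.ModelConfig(embed_dim=8, n_heads=2, n_tokens=4, encoder_count=1)
        p = make_params(cfg)
        x = rng.standard_normal((4, 8))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            encoder_block(x, np.ones(4), p, cfg, prefix="enc0_")

    def test_masked_softmax_rows_sum_to_one(self, rng):
        """Attention distributions over non-pad positions are normalized."""
        for _ in range(20):
            scores = Tensor(rng.standard_normal((5, 7)) * 3)
            mask = (rng.random(7) < 0.7).astype(float)
            mask[rng.integers(7)] = 1.0  # at least one real key
            probs = (scores + Tensor((1 - mask) * -1e9)).softmax(-1).data
            assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
            assert np.all(probs[:, mask == 0] < 1e-12)


# ---------------------------------------------------------------------------
# GAT
# ---------------------------------------------------------------------------


class TestGatLayer:
    def _cfg(self):
        return df.ModelConfig(embed_dim=8, n_heads=2, n_tokens=4, encoder_count=1)

    def test_isolated_node_self_attention_weight_is_one(self, rng):
        cfg = self._cfg()
        p = make_params(cfg, seed=3)
        feats = rng.random((3, 2))
        adj = np.zeros((3, 3))
        out = gat_layer(feats, adj, p, cfg, prefix="gat1_")
        ref, alphas = ref_gat(feats, adj, p, cfg, "gat1_")
        assert np.allclose(out.data, ref)
        assert all(alphas[i][i] == 1.0 for i in range(3))

    def test_two_identical_connected_nodes_share_weight(self, rng):
        cfg = self._cfg()
        p = make_params(cfg, seed=4)
        feat = rng.random(2)
        feats = np.stack([feat, feat])
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        _, alphas = ref_gat(feats, adj, p, cfg, "gat1_")
        assert np.allclose(list(alphas[0].values()), 0.5)
        out = gat_layer(feats, adj, p, cfg, prefix="gat1_")
        ref, _ = ref_gat(feats, adj, p, cfg, "gat1_")
        assert np.allclose(out.data, ref)

    def test_path_graph_matches_per_edge_oracle(self):
        cfg = self._cfg()
        p = make_params(cfg, seed=5)
        for name in ("W1", "W2"):  # fixed small integer weights
            p["gat1_" + name].data[:] = np.arange(p["gat1_" + name].data.size).reshape(
                p["gat1_" + name].data.shape
            ) % 3 - 1
        p["gat1_a"].data[:] = 1.0
        feats = np.array([[0.1, 0.9], [0.5, 0.5], [0.9, 0.1]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        out = gat_layer(feats, adj, p, cfg, prefix="gat1_")
        ref, alphas = ref_gat(feats, adj, p, cfg, "gat1_")
        assert np.allclose(out.data, ref, atol=1e-12)
        for i in alphas:
            assert np.isclose(sum(alphas[i].values()), 1.0, atol=1e-6)

    def test_asymmetric_adjacency_rejected(self, rng):
        cfg = self._cfg()
        p = make_params(cfg)
        adj = np.zeros((3, 3))
        adj[0, 1] = 1.0
        with pytest.raises(ValueError):
            gat_layer(rng.random((3, 2)), adj, p, cfg, prefix="gat1_")

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_equals_oracle_on_all_small_graphs(self, seed):
        """Random graphs with <= 5 nodes and random parameterizations."""
        rng = np.random.default_rng(seed)
        cfg = df.ModelConfig(embed_dim=4, n_heads=2, n_tokens=4, encoder_count=1)
        n = int(rng.integers(1, 6))
        upper = np.triu(rng.random((n, n)) < 0.5, k=1)
        adj = (upper | upper.T).astype(float)
        feats = rng.standard_normal((n, 2))
        p = make_params(cfg, feature_dim=2, seed=int(rng.integers(2**31)))
        out = gat_layer(feats, adj, p, cfg, prefix="gat1_")
        ref, alphas = ref_gat(feats, adj, p, cfg, "gat1_")
        assert np.allclose(out.data, ref, atol=1e-10)
        for i in alphas:
            assert np.isclose(sum(alphas[i].values()), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# alignment / fusion / head / loss
# ---------------------------------------------------------------------------


class TestAlignAndFuse:
    def test_pad_positions_become_zero_rows(self, rng):
        g = rng.standard_normal((3, 5))
        tokens = np.array([1, 3])  # 3 == pad_id
        out = align_node_embeddings(g, tokens, pad_id=3)
        assert np.allclose(out.data[0], g[1])
        assert np.all(out.data[1] == 0)

    def test_permuting_tokens_permutes_rows(self, rng):
        g = rng.standard_normal((6, 4))
        tokens = np.array([2, 0, 5, 1])
        perm = np.array([3, 0, 2, 1])
        out = align_node_embeddings(g, tokens, pad_id=6).data
        out_perm = align_node_embeddings(g, tokens[perm], pad_id=6).data
        assert np.allclose(out[perm], out_perm)

    def test_lookup_oracle(self, rng):
        g = rng.standard_normal((10, 4))
        tokens = rng.integers(0, 11, size=10)
        out = align_node_embeddings(g, tokens, pad_id=10).data
        lut = {i: g[i] for i in range(10)}
        lut[10] = np.zeros(4)
        assert np.allclose(out, np.stack([lut[t] for t in tokens]))

    def test_gated_aggregate_zero_inputs_zero_output(self):
        cfg = df.ModelConfig(embed_dim=4, n_heads=2, n_tokens=2, encoder_count=1)
        p = make_params(cfg)
        out = gated_aggregate(np.zeros((2, 4)), np.zeros((2, 4)), p, prefix="ga1_")
        assert np.all(out.data == 0)

    def test_gated_aggregate_outputs_nonnegative(self, rng):
        cfg = df.ModelConfig(embed_dim=4, n_heads=2, n_tokens=2, encoder_count=1)
        p = make_params(cfg, seed=6)
        out = gated_aggregate(rng.standard_normal((5, 2, 4)), rng.standard_normal((5, 2, 4)), p)
        assert out.data.min() >= 0

    def test_block_identity_projection_recovers_token_path(self, rng):
        """W3 = [I; 0] makes the fusion output exactly ReLU(token path)."""
        cfg = df.ModelConfig(embed_dim=4, n_heads=2, n_tokens=2, encoder_count=1)
        p = make_params(cfg)
        p["ga1_W3"].data[:] = np.vstack([np.eye(4), np.zeros((4, 4))])
        p["ga1_b3"].data[:] = 0.0
        t = rng.standard_normal((2, 4))
        g = rng.standard_normal((2, 4))
        out = gated_aggregate(t, g, p, prefix="ga1_")
        assert np.allclose(out.data, np.maximum(t, 0))

    def test_shape_mismatch_rejected(self, rng):
        cfg = df.ModelConfig(embed_dim=4, n_heads=2, n_tokens=2, encoder_count=1)
        p = make_params(cfg)
        with pytest.raises(ValueError):
            gated_aggregate(rng.random((2, 4)), rng.random((3, 4)), p)


class TestOutputHeadAndLoss:
    @pytest.mark.parametrize("normalization", ["sigmoid", "softmax"])
    def test_zero_weights_give_half_half(self, normalization, rng):
        cfg = df.ModelConfig(embed_dim=4, n_heads=2, n_tokens=3, encoder_count=1,
                             output_normalization=normalization)
        p = make_params(cfg)
        for name in ("out_W4", "out_b4", "out_W5", "out_b5"):
            p[name].data[:] = 0.0
        out = output_head(rng.standard_normal((3, 4)), p, cfg)
        assert np.allclose(out.data, [0.5, 0.5])

    def test_matches_formula_oracle(self, rng):
        cfg = df.ModelConfig(embed_dim=8, n_heads=2, n_tokens=4, encoder_count=1)
        p = make_params(cfg, seed=7)
        x = rng.standard_normal((4, 8))
        out = output_head(x, p, cfg)
        assert np.allclose(out.data, ref_output_head(x, p, cfg), atol=1e-12)

    def test_softmax_option_sums_to_one_sigmoid_in_open_interval(self, rng):
        for norm in ("sigmoid", "softmax"):
            cfg = df.ModelConfig(embed_dim=4, n_heads=2, n_tokens=2, encoder_count=1,
                                 output_normalization=norm)
            p = make_params(cfg, seed=8)
            out = output_head(rng.standard_normal((5, 2, 4)), p, cfg).data
            if norm == "softmax":
                assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-9)
            else:
                assert np.all((out > 0) & (out < 1))

    def test_cross_entropy_uniform_prediction(self):
        loss = cross_entropy(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert np.isclose(loss.data, 2 * np.log(2), atol=1e-9)

    def test_cross_entropy_perfect_prediction_limit(self):
        eps = 1e-6
        loss = cross_entropy(np.array([1 - eps, eps]), np.array([1.0, 0.0]))
        assert loss.data < 1e-5

    def test_cross_entropy_hand_evaluated(self):
        loss = cross_entropy(np.array([0.3, 0.8]), np.array([0.0, 1.0]))
        assert np.isclose(loss.data, -(np.log(0.7) + np.log(0.8)), atol=1e-9)

    def test_cross_entropy_rejects_non_one_hot(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.5]), np.array([0.5, 0.5]))


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------


def _prepared(tiny_dataset, tiny_graph, cfg):
    return prepare_dataset(tiny_dataset, tiny_graph, cfg)


class TestForward:
    def test_deterministic_given_params(self, tiny_dataset, tiny_graph, tiny_model_config):
        prep = _prepared(tiny_dataset, tiny_graph, tiny_model_config)
        p = make_params(tiny_model_config, vocab_size=len(prep.vocab), seed=9)
        batch = prep.tokens[:6]
        out1 = forward(batch, prep.graph, p, tiny_model_config, prep.vocab).data
        out2 = forward(batch, prep.graph, p, tiny_model_config, prep.vocab).data
        assert np.array_equal(out1, out2)

    def test_batch_independence(self, tiny_dataset, tiny_graph, tiny_model_config):
        prep = _prepared(tiny_dataset, tiny_graph, tiny_model_config)
        p = make_params(tiny_model_config, vocab_size=len(prep.vocab), seed=10)
        single = forward(prep.tokens[3:4], prep.graph, p, tiny_model_config, prep.vocab).data
        batched = forward(prep.tokens[:8], prep.graph, p, tiny_model_config, prep.vocab).data
        assert np.allclose(single[0], batched[3], atol=1e-12)

    def test_composition_oracle(self, tiny_dataset, tiny_graph, tiny_model_config):
        """forward equals an unbatched composition of the stage operations."""
        cfg = tiny_model_config
        prep = _prepared(tiny_dataset, tiny_graph, cfg)
        p = make_params(cfg, vocab_size=len(prep.vocab), seed=11)
        batch = prep.tokens[:5]
        got = forward(batch, prep.graph, p, cfg, prep.vocab).data
        g1 = gat_layer(prep.graph.node_features, prep.graph.adjacency, p, cfg, "gat1_")
        g2 = gat_layer(g1, prep.graph.adjacency, p, cfg, "gat2_")
        for b, tokens in enumerate(batch):
            mask = (tokens != prep.vocab.pad_id).astype(float)
            x = p["tok_emb"].data[tokens] + p["pos_emb"].data[np.arange(cfg.n_tokens)]
            x = Tensor(x * mask[:, None])
            x = encoder_block(x, mask, p, cfg, prefix="enc0_")
            gt1 = align_node_embeddings(g1, tokens, prep.vocab.pad_id)
            x = gated_aggregate(x, gt1, p, prefix="ga1_", mask=mask)
            gt2 = align_node_embeddings(g2, tokens, prep.vocab.pad_id)
            x = gated_aggregate(x, gt2, p, prefix="ga2_", mask=mask)
            x = encoder_block(x, mask, p, cfg, prefix="enc1_")
            expected = output_head(x, p, cfg).data
            assert np.allclose(got[b], expected, atol=1e-10)

    def test_gene_relabeling_consistency(self, tiny_dataset, tiny_model_config):
        """Renaming genes (consistently in vocabulary, graph, embeddings)
        leaves every cell's probabilities unchanged."""
        cfg = tiny_model_config
        ds = tiny_dataset
        # break expression ties: the rank order (hence the symbol sequence)
        # must be label-independent for the invariant to be meaningful
        jitter_rng = np.random.default_rng(99)
        expr = ds.expression * (1 + jitter_rng.random(ds.expression.shape) * 1e-6)
        ds = df.SyntheticDataset(
            expression=expr, labels=ds.labels, scores=ds.scores,
            gene_symbols=ds.gene_symbols, cell_ids=ds.cell_ids,
            signature_genes=ds.signature_genes,
        )
        graph = df.build_graph(ds.scores, tau=0.05)
        prep = prepare_dataset(ds, graph, cfg)
        p = make_params(cfg, vocab_size=len(prep.vocab), seed=12)
        base = forward(prep.tokens[:6], prep.graph, p, cfg, prep.vocab).data

        # rename so the sorted order reverses: gene i -> Z<reversed index>
        n = len(ds.gene_symbols)
        new_names = [f"Z{n - 1 - i:04d}" for i in range(n)]
        rename = dict(zip(ds.gene_symbols, new_names))
        ds2 = df.SyntheticDataset(
            expression=ds.expression, labels=ds.labels,
            scores=df.GeneScoreTable(
                symbols=[rename[s] for s in ds.scores.symbols],
                phaplo=ds.scores.phaplo, ptriplo=ds.scores.ptriplo,
            ),
            gene_symbols=[rename[s] for s in ds.gene_symbols],
            cell_ids=ds.cell_ids,
            signature_genes=[rename[s] for s in ds.signature_genes],
        )
        graph2 = df.build_graph(ds2.scores, tau=0.05)
        prep2 = prepare_dataset(ds2, graph2, cfg)
        # map old token id -> new token id and permute the embedding table
        old_to_new = {
            prep.vocab.symbol_to_id[s]: prep2.vocab.symbol_to_id[rename[s]]
            for s in ds.gene_symbols
        }
        p2 = make_params(cfg, vocab_size=len(prep2.vocab), seed=12)
        for k in p.tensors:
            p2.tensors[k].data = p.tensors[k].data.copy()
        for old, new in old_to_new.items():
            p2["tok_emb"].data[new] = p["tok_emb"].data[old]
        out = forward(prep2.tokens[:6], prep2.graph, p2, cfg, prep2.vocab).data
        assert np.allclose(base, out, atol=1e-10)

    def test_ablated_model_ignores_graph(self, tiny_dataset, tiny_graph, tiny_model_config):
        cfg = tiny_model_config
        prep = _prepared(tiny_dataset, tiny_graph, cfg)
        p = make_params(cfg, vocab_size=len(prep.vocab), seed=13)
        out1 = forward(prep.tokens[:4], prep.graph, p, cfg, prep.vocab, ablate_graph=True).data
        # scramble the graph: the ablated forward must not change
        scrambled = df.KnowledgeGraph(
            genes=prep.graph.genes,
            adjacency=np.zeros_like(prep.graph.adjacency),
            node_features=prep.graph.node_features + 5.0,
        )
        out2 = forward(prep.tokens[:4], scrambled, p, cfg, prep.vocab, ablate_graph=True).data
        assert np.array_equal(out1, out2)

    def test_unrestricted_graph_rejected(self, tiny_dataset, tiny_graph, tiny_model_config):
        cfg = tiny_model_config
        prep = _prepared(tiny_dataset, tiny_graph, cfg)
        p = make_params(cfg, vocab_size=len(prep.vocab), seed=14)
        bad = df.KnowledgeGraph(
            genes=prep.graph.genes[::-1],
            adjacency=prep.graph.adjacency,
            node_features=prep.graph.node_features,
        )
        with pytest.raises(ValueError):
            forward(prep.tokens[:2], bad, p, cfg, prep.vocab)


class TestLeakyRelu:
    @pytest.mark.parametrize(
        "x,expected", [(2.0, 2.0), (-1.0, -0.2), (0.0, 0.0)]
    )
    def test_case_split(self, x, expected):
        assert leaky_relu(x, 0.2) == pytest.approx(expected)
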