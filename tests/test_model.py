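"""Architecture tests: shape laws, projection math, cross-attention against
a scalar-loop oracle, fusion/encoder variants, and embedding regularization."""

import numpy as np
import pytest

from transbind import ModelConfig, PairwiseTransBind, TransBindModel, regularize_embedding
from transbind.model import DNAEncoder
from transbind.nn import Dense, MultiheadAttention, Tensor


def tiny_config(**overrides):
    base = dict(
        input_len=120, conv_filters=10, conv_kernel=8, pool_window=5,
        lstm_hidden_per_dir=6, lstm_layers=1, transformer_heads=3,
        transformer_ffn=16, d2=16, cross_attn_heads=4, dropout_p=0.0,
        n_labels=3, seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base).validate()


def naive_multihead_attention(mha: MultiheadAttention, q: np.ndarray,
                              kv: np.ndarray) -> np.ndarray:
    """Scalar-loop oracle for one (T, qdim) query set over (L, kvdim)."""
    Wq, Wk, Wv, Wo = (mha.w_q.weight.data, mha.w_k.weight.data,
                      mha.w_v.weight.data, mha.w_o.weight.data)
    Q, K, V = q @ Wq, kv @ Wk, kv @ Wv
    T, L = len(q), len(kv)
    h, dh = mha.heads, mha.d_head
    merged = np.zeros((T, h * dh))
    for t in range(T):
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            scores = np.array([
                sum(Q[t, sl][i] * K[l, sl][i] for i in range(dh)) / np.sqrt(dh)
                for l in range(L)
            ])
            e = np.exp(scores - scores.max())
            w = e / e.sum()
            for l in range(L):
                merged[t, sl] += w[l] * V[l, sl]
    return merged @ Wo


class TestShapeLaw:
    @pytest.mark.parametrize("input_len,expected_L",
                             [(500, 36), (800, 59), (1000, 75), (1200, 90)])
    def test_default_architecture_pooled_length(self, input_len, expected_L):
        cfg = ModelConfig(input_len=input_len, n_labels=2)
        assert cfg.effective_length == expected_L
        assert cfg.effective_length == (input_len - 26 + 1) // 13

    def test_full_size_encoder_produces_75_positions(self):
        cfg = ModelConfig(n_labels=2).validate()
        enc = DNAEncoder(cfg, np.random.default_rng(0))
        x = np.zeros((2, 1000, 4))
        x[:, :, 0] = 1
        rep = enc.encode(x)
        assert rep.H.shape == (2, 75, 320)
        assert rep.x1.shape == (2, 320)
        assert np.allclose(rep.x1, rep.H.mean(axis=1), atol=1e-6)

    def test_small_encoder_shapes_and_finiteness(self):
        cfg = tiny_config()
        enc = DNAEncoder(cfg, np.random.default_rng(1))
        rep = enc.encode(np.zeros((3, cfg.input_len, 4)))
        L = (cfg.input_len - cfg.conv_kernel + 1) // cfg.pool_window
        assert rep.H.shape == (3, L, cfg.d1)
        assert np.isfinite(rep.H).all() and np.isfinite(rep.x1).all()

    def test_input_shorter_than_kernel_errors(self):
        with pytest.raises(ValueError):
            ModelConfig(input_len=20, conv_kernel=26, n_labels=1).validate()


class TestProjection:
    def project(self, W, b, e):
        d1, d2 = np.asarray(W).shape
        layer = Dense(d2, d1, np.random.default_rng(0))
        layer.weight.data[...] = np.asarray(W, dtype=float).T
        layer.bias.data[...] = np.asarray(b, dtype=float)
        return layer(Tensor(np.asarray(e, dtype=float).reshape(1, -1))).data[0]

    def test_selector_matrix(self):
        out = self.project([[1, 0, 0], [0, 1, 0]], [0, 0], [5, 7, 9])
        assert np.allclose(out, [5, 7])

    def test_zero_embedding_returns_bias(self):
        out = self.project([[1, 1, 1], [2, 0, -1]], [3, -4], [0, 0, 0])
        assert np.allclose(out, [3, -4])

    def test_hand_computed_product(self):
        out = self.project([[1, 1, 1], [2, 0, -1]], [1, -1], [1, 2, 3])
        assert np.allclose(out, [7, -2])


class TestCrossAttention:
    def test_identical_value_rows_dominate_any_query(self):
        rng = np.random.default_rng(2)
        mha = MultiheadAttention(6, 6, 8, 2, rng)
        kv = np.tile(rng.normal(size=(1, 6)), (5, 1))  # all rows equal
        q = rng.normal(size=(1, 3, 6))
        out = mha(Tensor(q), Tensor(kv[None, :, :])).data[0]
        expected = naive_multihead_attention(mha, q[0], kv)
        assert np.allclose(out, expected, atol=1e-9)
        assert np.allclose(out[0], out[1])  # query-independent

    def test_single_position_passthrough(self):
        rng = np.random.default_rng(3)
        mha = MultiheadAttention(6, 6, 8, 2, rng)
        kv = rng.normal(size=(1, 1, 6))
        q = rng.normal(size=(1, 2, 6))
        out = mha(Tensor(q), Tensor(kv)).data[0]
        projected = (kv[0] @ mha.w_v.weight.data) @ mha.w_o.weight.data
        assert np.allclose(out[0], projected[0], atol=1e-9)
        assert np.allclose(out[1], projected[0], atol=1e-9)

    @pytest.mark.parametrize("heads,dim,T,L", [(1, 2, 1, 2), (2, 8, 3, 5),
                                               (4, 8, 2, 7)])
    def test_matches_scalar_loop_oracle(self, heads, dim, T, L):
        rng = np.random.default_rng(heads * 10 + L)
        mha = MultiheadAttention(5, 7, dim, heads, rng)
        q = rng.normal(size=(T, 5))
        kv = rng.normal(size=(L, 7))
        fast = mha(Tensor(q[None]), Tensor(kv[None])).data[0]
        slow = naive_multihead_attention(mha, q, kv)
        assert np.allclose(fast, slow, atol=1e-9)

    def test_key_row_permutation_invariance(self):
        # attention is content-based: permuting key/value rows permutes the
        # softmax weights with them, leaving each attended row unchanged
        rng = np.random.default_rng(4)
        mha = MultiheadAttention(6, 6, 8, 2, rng)
        kv = rng.normal(size=(1, 6, 6))
        q = rng.normal(size=(1, 2, 6))
        out = mha(Tensor(q), Tensor(kv)).data
        shuffled = kv[:, ::-1, :].copy()
        out2 = mha(Tensor(q), Tensor(shuffled)).data
        assert np.allclose(out, out2, atol=1e-9)

    def test_position_sensitivity_enters_through_encoder(self):
        # the fused model must react to where in the window content sits,
        # which the convolution + BiLSTM stages provide
        cfg = tiny_config()
        model = TransBindModel(cfg, np.random.default_rng(0).normal(
            size=(cfg.n_labels, cfg.d2)))
        rng = np.random.default_rng(1)
        idx = rng.integers(0, 4, cfg.input_len)
        x = np.zeros((1, cfg.input_len, 4))
        x[0, np.arange(cfg.input_len), idx] = 1
        out = model(x).data
        perm = rng.permutation(cfg.input_len)
        out2 = model(x[:, perm, :]).data
        assert not np.allclose(out, out2)


class TestMultilabelModel:
    def test_zero_head_weights_give_bias_logits(self):
        cfg = tiny_config()
        model = TransBindModel(cfg, np.random.default_rng(5).normal(
            size=(cfg.n_labels, cfg.d2)))
        model.head.weight.data[...] = 0.0
        model.head.bias.data[...] = np.array([0.5, -1.0, 2.0])
        logits = model(np.zeros((2, cfg.input_len, 4))).data
        assert np.allclose(logits, [[0.5, -1.0, 2.0]] * 2)

    def test_eval_purity(self):
        cfg = tiny_config()
        model = TransBindModel(cfg, np.random.default_rng(6).normal(
            size=(cfg.n_labels, cfg.d2)))
        x = np.random.default_rng(7).integers(0, 2, (2, cfg.input_len, 4))
        a = model(x.astype(float)).data
        b = model(x.astype(float)).data
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("fusion", ["cross_attention", "bidirectional",
                                        "concat"])
    @pytest.mark.parametrize("encoder", ["full", "lstm_only",
                                         "transformer_only", "sequence_only"])
    def test_all_variant_combinations_run(self, fusion, encoder):
        cfg = tiny_config(fusion_mode=fusion, encoder_mode=encoder,
                          conv_filters=12)
        model = TransBindModel(cfg, np.random.default_rng(8).normal(
            size=(cfg.n_labels, cfg.d2)))
        out = model(np.zeros((1, cfg.input_len, 4))).data
        assert out.shape == (1, cfg.n_labels)
        assert np.isfinite(out).all()

    def test_head_affine_hand_example(self):
        layer = Dense(4, 1, np.random.default_rng(0))
        layer.weight.data[:, 0] = [1, 2, 3, 4]
        layer.bias.data[...] = 0.0
        out = layer(Tensor(np.array([[1.0, 0.0, 0.0, 1.0]]))).data
        assert out[0, 0] == pytest.approx(5.0)


class TestPairwiseModel:
    def test_identical_embeddings_identical_logits(self):
        cfg = tiny_config(n_labels=1)
        model = PairwiseTransBind(cfg)
        x = np.random.default_rng(9).integers(0, 2, (1, cfg.input_len, 4))
        e = np.random.default_rng(10).normal(size=(1, cfg.d2))
        x2 = np.concatenate([x, x])
        e2 = np.concatenate([e, e])
        logits = model(x2.astype(float), e2).data
        assert logits[0] == pytest.approx(logits[1])
        again = model(x2.astype(float), e2).data
        assert np.array_equal(logits, again)

    def test_finite_over_random_draws(self):
        cfg = tiny_config(n_labels=1)
        model = PairwiseTransBind(cfg)
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, (50, cfg.input_len, 4)).astype(float)
        e = rng.normal(size=(50, cfg.d2))
        assert np.isfinite(model(x, e).data).all()

    def test_embedding_dim_mismatch_errors(self):
        cfg = tiny_config(n_labels=1)
        model = PairwiseTransBind(cfg)
        with pytest.raises(ValueError):
            model(np.zeros((1, cfg.input_len, 4)), np.zeros((1, cfg.d2 + 1)))


class TestRegularizeEmbedding:
    def test_mask_everything(self):
        rng = np.random.default_rng(0)
        out = regularize_embedding(np.ones((20, 8)), 1.0, 0.5, rng)
        assert np.array_equal(out, np.zeros((20, 8)))

    def test_identity_when_disabled(self):
        rng = np.random.default_rng(0)
        x = np.random.default_rng(1).normal(size=(10, 8))
        assert np.array_equal(regularize_embedding(x, 0.0, 0.0, rng), x)

    def test_masked_fraction_binomial(self):
        rng = np.random.default_rng(2)
        n, p = 10_000, 0.05
        out = regularize_embedding(np.ones((n, 4)), p, 0.01, rng)
        masked = (out == 0).all(axis=1).mean()
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(masked - p) < 3 * sd


class TestCheckpointRoundtrip:
    def test_multilabel_roundtrip(self, tmp_path):
        from transbind import load_checkpoint, save_checkpoint

        cfg = tiny_config()
        model = TransBindModel(cfg, np.random.default_rng(12).normal(
            size=(cfg.n_labels, cfg.d2)))
        x = np.random.default_rng(13).integers(
            0, 2, (2, cfg.input_len, 4)).astype(float)
        before = model(x).data
        path = str(tmp_path / "model.npz")
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert np.allclose(restored(x).data, before)
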