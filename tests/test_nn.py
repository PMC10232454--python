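import numpy as np
import pytest

from smilesrl import nn
from smilesrl.nn import DecoderConfig


def tiny_cfg(**kw):
    base = dict(vocab_size=7, n_layers=2, n_heads=2, d_model=8, d_ff=16,
                max_len=12, dropout=0.0)
    base.update(kw)
    return DecoderConfig(**base)


class TestConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            tiny_cfg(d_model=10, n_heads=4)

    def test_max_len_floor(self):
        with pytest.raises(ValueError, match="max_len"):
            tiny_cfg(max_len=1)

    def test_round_trip_dict(self):
        cfg = tiny_cfg()
        assert DecoderConfig.from_dict(cfg.to_dict()) == cfg


class TestAttention:
    def test_single_position_is_identity(self):
        out = nn.attention(np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]]))
        assert np.allclose(out, [[1.0]])

    def test_causal_row_zero_sees_only_itself(self, rng):
        Q, K = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        V1, V2 = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        V2[0] = V1[0]  # only the future row differs
        m = nn.causal_mask(2)
        out1, out2 = nn.attention(Q, K, V1, m), nn.attention(Q, K, V2, m)
        assert np.allclose(out1[0], out2[0])

    def test_matches_double_loop_oracle(self, rng):
        T, d = 4, 8
        Q, K, V = rng.normal(size=(T, d)), rng.normal(size=(T, d)), rng.normal(size=(T, d))
        mask = nn.causal_mask(T)
        expected = np.zeros((T, d))
        for i in range(T):
            scores = np.array([
                Q[i] @ K[j] / np.sqrt(d) if mask[i, j] else -np.inf for j in range(T)
            ])
            w = np.exp(scores - scores.max())
            w /= w.sum()
            for j in range(T):
                expected[i] += w[j] * V[j]
        assert np.allclose(nn.attention(Q, K, V, mask), expected)

    def test_rows_sum_to_one_over_unmasked(self, rng):
        # weights applied to an all-ones V must return exactly ones
        T, d = 5, 4
        Q, K = rng.normal(size=(T, d)), rng.normal(size=(T, d))
        out = nn.attention(Q, K, np.ones((T, d)), nn.causal_mask(T))
        assert np.allclose(out, 1.0, atol=1e-12)


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_attention(self, rng):
        cfg = tiny_cfg(n_layers=1, n_heads=1)
        p = nn.init_params(cfg, rng)
        D = cfg.d_model
        for nm in ("wq", "wk", "wv", "wo"):
            p[f"l0.attn.{nm}"] = np.eye(D)
        for nm in ("bq", "bk", "bv", "bo"):
            p[f"l0.attn.{nm}"] = np.zeros(D)
        x = rng.normal(size=(5, D))
        out = nn.multi_head_attention(x, p, "l0.attn", 1)
        assert np.allclose(out, nn.attention(x, x, x, nn.causal_mask(5)))

    def test_agrees_with_per_head_loop(self, rng):
        cfg = tiny_cfg(n_layers=1)
        p = nn.init_params(cfg, rng)
        D, H = cfg.d_model, cfg.n_heads
        dh = D // H
        x = rng.normal(size=(6, D))
        q = x @ p["l0.attn.wq"] + p["l0.attn.bq"]
        k = x @ p["l0.attn.wk"] + p["l0.attn.bk"]
        v = x @ p["l0.attn.wv"] + p["l0.attn.bv"]
        mask = nn.causal_mask(6)
        heads = [
            nn.attention(q[:, h * dh:(h + 1) * dh], k[:, h * dh:(h + 1) * dh],
                         v[:, h * dh:(h + 1) * dh], mask)
            for h in range(H)
        ]
        expected = np.concatenate(heads, axis=1) @ p["l0.attn.wo"] + p["l0.attn.bo"]
        assert np.allclose(nn.multi_head_attention(x, p, "l0.attn", H), expected)

    def test_causal_invariance_to_future_edit(self, rng):
        cfg = tiny_cfg(n_layers=1)
        p = nn.init_params(cfg, rng)
        x = rng.normal(size=(6, cfg.d_model))
        y = x.copy()
        y[4:] += rng.normal(size=(2, cfg.d_model))
        o1 = nn.multi_head_attention(x, p, "l0.attn", cfg.n_heads)
        o2 = nn.multi_head_attention(y, p, "l0.attn", cfg.n_heads)
        assert np.allclose(o1[:4], o2[:4])


class TestDecoderBlock:
    def test_zeroed_sublayers_give_identity(self, rng):
        cfg = tiny_cfg(n_layers=1)
        p = nn.init_params(cfg, rng)
        p["l0.attn.wo"][:] = 0.0
        p["l0.attn.bo"][:] = 0.0
        p["l0.mlp.w2"][:] = 0.0
        p["l0.mlp.b2"][:] = 0.0
        x = rng.normal(size=(5, cfg.d_model))
        assert np.allclose(nn.decoder_block(x, p, 0, cfg.n_heads), x)

    def test_stack_preserves_shape(self, rng):
        cfg = tiny_cfg()
        p = nn.init_params(cfg, rng)
        x = rng.normal(size=(4, cfg.d_model))
        for i in range(cfg.n_layers):
            x = nn.decoder_block(x, p, i, cfg.n_heads)
        assert x.shape == (4, cfg.d_model)


class TestForward:
    def test_distribution_rows_sum_to_one(self, rng):
        cfg = tiny_cfg()
        p = nn.init_params(cfg, rng)
        ids = rng.integers(0, cfg.vocab_size, size=(3, 6))
        probs = nn.softmax(nn.forward(p, cfg, ids))
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_causality_through_full_stack(self, rng):
        cfg = tiny_cfg()
        p = nn.init_params(cfg, rng)
        ids = rng.integers(0, cfg.vocab_size, size=(1, 6))
        edited = ids.copy()
        edited[0, 4] = (ids[0, 4] + 1) % cfg.vocab_size
        l1 = nn.forward(p, cfg, ids)
        l2 = nn.forward(p, cfg, edited)
        assert np.allclose(l1[0, :4], l2[0, :4])
        assert not np.allclose(l1[0, 4:], l2[0, 4:])

    def test_zeroed_head_is_uniform(self, rng):
        cfg = tiny_cfg()
        p = nn.init_params(cfg, rng)
        p["head.w"][:] = 0.0
        p["head.b"][:] = 0.0
        probs = nn.softmax(nn.forward(p, cfg, rng.integers(0, 7, size=(2, 4))))
        assert np.allclose(probs, 1.0 / cfg.vocab_size)

    def test_overlength_input_rejected(self, rng):
        cfg = tiny_cfg(max_len=4)
        p = nn.init_params(cfg, rng)
        with pytest.raises(ValueError, match="max_len"):
            nn.forward(p, cfg, np.zeros((1, 5), dtype=int))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        cfg = tiny_cfg()
        p = nn.init_params(cfg, rng)
        ids = rng.integers(0, cfg.vocab_size, size=(3, 5))
        tgt = rng.integers(0, cfg.vocab_size, size=(3, 5))
        tgt[0, 4] = -1  # exercise the ignore path
        w = rng.random((3, 5))
        _, grads = nn.weighted_nll_loss(p, cfg, ids, tgt, w)
        h = 1e-6
        check_rng = np.random.default_rng(1)
        for key in p:
            flat = p[key].reshape(-1)
            for i in check_rng.integers(0, flat.size, size=3):
                orig = flat[i]
                flat[i] = orig + h
                up, _ = nn.weighted_nll_loss(p, cfg, ids, tgt, w)
                flat[i] = orig - h
                lo, _ = nn.weighted_nll_loss(p, cfg, ids, tgt, w)
                flat[i] = orig
                fd = (up - lo) / (2 * h)
                assert grads[key].reshape(-1)[i] == pytest.approx(fd, abs=1e-7, rel=1e-5), key

    def test_dropout_backward_matches_finite_differences(self, rng):
        # dropout masks must be identical across evaluations: fix the rng seed
        cfg = tiny_cfg(dropout=0.2)
        p = nn.init_params(cfg, rng)
        ids = rng.integers(0, cfg.vocab_size, size=(2, 4))
        tgt = rng.integers(0, cfg.vocab_size, size=(2, 4))

        def loss_at(params):
            return nn.weighted_nll_loss(params, cfg, ids, tgt, train=True,
                                        rng=np.random.default_rng(7))

        _, grads = loss_at(p)
        h = 1e-6
        flat = p["l0.mlp.w1"].reshape(-1)
        i = 5
        orig = flat[i]
        flat[i] = orig + h
        up, _ = loss_at(p)
        flat[i] = orig - h
        lo, _ = loss_at(p)
        flat[i] = orig
        assert grads["l0.mlp.w1"].reshape(-1)[i] == pytest.approx((up - lo) / (2 * h), abs=1e-7, rel=1e-5)


class TestAdam:
    def test_zero_gradient_leaves_params_fixed(self, rng):
        cfg = tiny_cfg()
        p = nn.init_params(cfg, rng)
        before = {k: v.copy() for k, v in p.items()}
        opt = nn.Adam(lr=0.1)
        opt.step(p, {k: np.zeros_like(v) for k, v in p.items()})
        for k in p:
            assert np.array_equal(p[k], before[k])

    def test_descends_a_quadratic(self):
        p = {"x": np.array([5.0])}
        opt = nn.Adam(lr=0.1)
        for _ in range(500):
            opt.step(p, {"x": 2 * p["x"]})
        assert abs(p["x"][0]) < 1e-2
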