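"""Transformer internals: pooling, cosine loss, schedule, and exact gradients."""

import math

import numpy as np
import pytest

from crxnfp.nn import (
    TransformerEncoderModel,
    WarmupLinearSchedule,
    cosine,
    cosine_mse_loss,
    mean_pool,
)


class TestMeanPool:
    def test_single_token_returns_its_vector(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(mean_pool(v, np.array([1.0])), v[0])

    def test_opposite_vectors_cancel(self):
        v = np.array([[1.0, -2.0], [-1.0, 2.0]])
        assert np.allclose(mean_pool(v, np.array([1.0, 1.0])), 0.0)

    def test_padded_batch_equals_per_sequence_means(self):
        rng = np.random.default_rng(0)
        batch = rng.normal(size=(4, 7, 5))
        lengths = [7, 3, 5, 1]
        mask = np.zeros((4, 7))
        for i, n in enumerate(lengths):
            mask[i, :n] = 1.0
        pooled = mean_pool(batch, mask)
        for i, n in enumerate(lengths):
            assert np.allclose(pooled[i], batch[i, :n].mean(axis=0))

    def test_fully_masked_sequence_is_error(self):
        with pytest.raises(ValueError):
            mean_pool(np.ones((2, 3)), np.zeros(2))


class TestCosine:
    def test_identities(self):
        a = np.array([1.0, 2.0, 0.0])
        assert cosine(a, a) == pytest.approx(1.0)
        assert cosine(a, -a) == pytest.approx(-1.0)
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 5.0])) == pytest.approx(0.0)

    def test_zero_vector_is_error(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(3), np.ones(3))

    def test_loss_at_identical_pairs_equals_closed_form(self):
        """A batch of identical embeddings with the top transformed target:
        the residual is exactly 1 - (1 - e^-5)."""
        u = np.array([[1.0, 2.0], [3.0, -1.0]])
        target = 1.0 - math.exp(-5.0)
        loss, cos, _, _ = cosine_mse_loss(u, u.copy(), np.full(2, target))
        assert np.allclose(cos, 1.0)
        assert loss == pytest.approx((1.0 - target) ** 2)

    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(3, 4))
        v = rng.normal(size=(3, 4))
        t = rng.uniform(0, 0.99, 3)
        _, _, du, dv = cosine_mse_loss(u, v, t)
        eps = 1e-7
        for arr, grad in ((u, du), (v, dv)):
            for i in (0, 1):
                for j in (0, 3):
                    orig = arr[i, j]
                    arr[i, j] = orig + eps
                    lp = cosine_mse_loss(u, v, t)[0]
                    arr[i, j] = orig - eps
                    lm = cosine_mse_loss(u, v, t)[0]
                    arr[i, j] = orig
                    assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestSchedule:
    def test_warmup_then_linear_decay_to_zero(self):
        sched = WarmupLinearSchedule(max_lr=1e-3, total_steps=100, warmup_fraction=0.1)
        assert sched.lr(1) == pytest.approx(1e-4)
        assert sched.lr(10) == pytest.approx(1e-3)
        assert sched.lr(55) == pytest.approx(1e-3 * 45 / 90)
        assert sched.lr(100) == pytest.approx(0.0)

    def test_invalid_warmup_rejected(self):
        with pytest.raises(ValueError):
            WarmupLinearSchedule(1e-3, 100, warmup_fraction=0.0)


class TestGradients:
    def test_backward_matches_numerical_gradients(self):
        """End-to-end gradient check of the full encoder + pooling + cosine loss."""
        rng = np.random.default_rng(0)
        model = TransformerEncoderModel(
            vocab_size=12, n_layers=2, hidden_size=8, ffn_size=16, n_heads=2,
            max_len=10, seed=1,
        )
        B, T = 3, 6
        ids_a = rng.integers(0, 12, (B, T))
        ids_b = rng.integers(0, 12, (B, T))
        mask_a = np.ones((B, T)); mask_a[0, 4:] = 0
        mask_b = np.ones((B, T)); mask_b[1, 5:] = 0
        pool_a = mask_a.copy(); pool_a[:, 0] = 0
        pool_b = mask_b.copy(); pool_b[:, 0] = 0
        targets = rng.uniform(0, 0.99, B)

        def pool(h, m):
            return (h * m[:, :, None]).sum(axis=1) / m.sum(axis=1)[:, None]

        def pool_back(d, m):
            return m[:, :, None] * d[:, None, :] / m.sum(axis=1)[:, None, None]

        def loss_and_grads():
            ha, ca = model.forward(ids_a, mask_a)
            hb, cb = model.forward(ids_b, mask_b)
            loss, _, du, dv = cosine_mse_loss(pool(ha, pool_a), pool(hb, pool_b), targets)
            ga = model.backward(ca, pool_back(du, pool_a))
            gb = model.backward(cb, pool_back(dv, pool_b))
            return loss, {k: ga[k] + gb[k] for k in ga}

        _, grads = loss_and_grads()
        eps = 1e-6
        checked = 0
        for name in (
            "tok_emb", "pos_emb", "ln_emb.g", "layer0.Wq", "layer0.bk",
            "layer1.Wo", "layer1.W1", "layer1.b2", "layer1.ln2.g", "layer0.ln1.b",
        ):
            flat = model.params[name].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_and_grads()[0]
                flat[i] = orig - eps
                lm = loss_and_grads()[0]
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name].ravel()[i]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked >= 30

    def test_attention_rows_sum_to_one(self):
        model = TransformerEncoderModel(
            vocab_size=10, n_layers=2, hidden_size=8, ffn_size=16, n_heads=2, seed=0
        )
        ids = np.array([[1, 4, 5, 6, 0, 0]])
        mask = np.array([[1.0, 1, 1, 1, 0, 0]])
        _, cache = model.forward(ids, mask)
        for att in cache["attn"]:
            assert np.allclose(att.sum(axis=-1), 1.0)
            # no attention leaks onto padded key positions
            assert np.allclose(att[..., 4:], 0.0, atol=1e-12)

    def test_hidden_size_must_divide_heads(self):
        with pytest.raises(ValueError):
            TransformerEncoderModel(10, 1, 10, 20, 4)
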