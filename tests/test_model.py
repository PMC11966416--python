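"""Model architecture properties: ProbSparse attention vs dense softmax,
encoder distilling arithmetic, decoder causality, fusion geometry, dual
heads, end-to-end gradients, and training determinism (at reduced width)."""

import numpy as np
import pytest

from vmatqa.nn.autograd import Tensor, default_dtype, get_default_dtype
from vmatqa.nn.informer import probsparse_attention, sinusoidal_encoding
from vmatqa.nn.layers import Conv2d, LSTM, avg_pool2d, max_pool1d
from vmatqa.nn.models import (
    Adam,
    CNNModel,
    InformerCNN,
    InformerModel,
    LSTMModel,
    ModelConfig,
    build_model,
    joint_loss,
    load_checkpoint,
    predict_arrays,
    save_checkpoint,
    train,
)

rng = np.random.default_rng(0)

SMALL = dict(d_model=32, ffn_dim=64, window=8, conv_channels=(4, 4, 4),
             lstm_hidden=16, head_hidden=16, seed=3)


def make_arrays(n, W=8, seed=0):
    r = np.random.default_rng(seed)
    dt = get_default_dtype()
    return {
        "L": r.normal(size=(n, W, 141)).astype(dt),
        "C": r.normal(size=(n, 31)).astype(dt),
        "R": r.normal(size=(n, 107)).astype(dt),
        "D": r.normal(size=(n, 93)).astype(dt),
        "cal": r.normal(size=(n, W, 3)).astype(dt),
    }


def dense_attention(q, k, v):
    d = q.shape[-1]
    s = (q @ np.swapaxes(k, -1, -2)) / np.sqrt(d)
    e = np.exp(s - s.max(-1, keepdims=True))
    a = e / e.sum(-1, keepdims=True)
    return a @ v


class TestProbSparse:
    def test_equals_dense_at_full_u_50_instances(self):
        """ProbSparse with u = L_Q reproduces dense attention to 1e-6."""
        for i in range(50):
            r = np.random.default_rng(i)
            B, H, L, d = 1 + i % 3, 1 + i % 2, 4 + i % 9, 4 + i % 5
            q, k, v = (r.normal(size=(B, H, L, d)) for _ in range(3))
            out = probsparse_attention(Tensor(q), Tensor(k), Tensor(v), u=L)
            np.testing.assert_allclose(out.data, dense_attention(q, k, v),
                                       atol=1e-6)

    def test_identical_keys_give_mean_of_values(self):
        q = rng.normal(size=(1, 1, 6, 4))
        k = np.broadcast_to(rng.normal(size=(1, 1, 1, 4)), (1, 1, 6, 4)).copy()
        v = rng.normal(size=(1, 1, 6, 4))
        out = probsparse_attention(Tensor(q), Tensor(k), Tensor(v), u=3)
        np.testing.assert_allclose(
            out.data, np.broadcast_to(v.mean(axis=2, keepdims=True), v.shape),
            atol=1e-6)

    def test_single_query_key_returns_value(self):
        q = rng.normal(size=(1, 1, 1, 4))
        k = rng.normal(size=(1, 1, 1, 4))
        v = rng.normal(size=(1, 1, 1, 4))
        out = probsparse_attention(Tensor(q), Tensor(k), Tensor(v), u=1)
        np.testing.assert_allclose(out.data, v, atol=1e-7)

    def test_u_clamped_with_warning(self):
        q, k, v = (Tensor(rng.normal(size=(1, 1, 4, 4))) for _ in range(3))
        with pytest.warns(UserWarning, match="clamping"):
            probsparse_attention(q, k, v, u=99)

    def test_causal_mask_blocks_future(self):
        """Perturbing future positions leaves earlier causal-attention
        outputs unchanged."""
        L = 8
        q, k, v = (rng.normal(size=(1, 1, L, 4)) for _ in range(3))
        base = probsparse_attention(Tensor(q), Tensor(k), Tensor(v), u=L,
                                    causal=True).data
        k2, v2 = k.copy(), v.copy()
        k2[:, :, -2:, :] += 5.0
        v2[:, :, -2:, :] -= 3.0
        pert = probsparse_attention(Tensor(q), Tensor(k2), Tensor(v2), u=L,
                                    causal=True).data
        np.testing.assert_allclose(base[:, :, :L - 2], pert[:, :, :L - 2],
                                   atol=1e-7)
        assert not np.allclose(base[:, :, -1], pert[:, :, -1])

    def test_causal_fallback_is_cumulative_mean(self):
        """With u=1 only one query row gets softmax attention; the rest
        output the running mean of V."""
        L = 6
        q, k, v = (rng.normal(size=(1, 1, L, 4)) for _ in range(3))
        out = probsparse_attention(Tensor(q), Tensor(k), Tensor(v), u=1,
                                   causal=True)
        cum = np.cumsum(v, axis=2) / np.arange(1, L + 1)[None, None, :, None]
        matches = np.isclose(out.data, cum, atol=1e-6).all(axis=-1)[0, 0]
        assert matches.sum() >= L - 1


class TestEncoderDecoder:
    def test_distil_halves_sequence(self):
        from vmatqa.nn.informer import InformerEncoder

        r = np.random.default_rng(1)
        enc = InformerEncoder(141, 32, 4, 64, 2, 5.0, 0.0, r)
        for W, expect in [(32, 16), (30, 15), (8, 4)]:
            x = Tensor(np.random.default_rng(2).normal(size=(2, W, 141)))
            out, _ = enc(x, None, None, False)
            assert out.shape == (2, expect, 32)

    def test_window_below_four_rejected(self):
        from vmatqa.nn.informer import InformerEncoder

        enc = InformerEncoder(141, 16, 4, 32, 2, 5.0, 0.0,
                              np.random.default_rng(0))
        with pytest.raises(ValueError, match="distil"):
            enc(Tensor(np.zeros((1, 3, 141))), None, None, False)

    def test_decoder_causality(self):
        """Zeroing future positions of the start token does not change the
        self-attention contribution of earlier positions: outputs at the
        final (placeholder) position may differ, but an altered *past* does
        change it -- verify the mask direction both ways."""
        cfg = ModelConfig(**SMALL)
        m = InformerCNN(cfg)
        arrays = make_arrays(1, W=cfg.window, seed=5)
        base = m.summary_vector({k: Tensor(v) for k, v in arrays.items()},
                                None, False).data
        # altering the last (most recent) start-token day changes the summary
        pert = {k: v.copy() for k, v in arrays.items()}
        pert["L"][:, -1, :] += 1.0
        changed = m.summary_vector({k: Tensor(v) for k, v in pert.items()},
                                   None, False).data
        assert not np.allclose(base, changed, atol=1e-7)

    def test_summary_shape_for_various_windows(self):
        for W in (4, 8, 16):
            cfg = ModelConfig(**{**SMALL, "window": W})
            m = InformerCNN(cfg)
            arrays = make_arrays(2, W=W, seed=1)
            out = m.summary_vector({k: Tensor(v) for k, v in arrays.items()},
                                   None, False)
            assert out.shape == (2, cfg.d_model)

    def test_batch_independence(self):
        cfg = ModelConfig(**SMALL)
        m = InformerCNN(cfg)
        arrays = make_arrays(4, W=cfg.window, seed=2)
        full, _ = m({k: Tensor(v) for k, v in arrays.items()}, None, False)
        perm = [2, 0, 3, 1]
        permuted, _ = m({k: Tensor(v[perm]) for k, v in arrays.items()},
                        None, False)
        np.testing.assert_allclose(permuted.data, full.data[perm], atol=1e-5)

    def test_sinusoidal_encoding_bounded(self):
        enc = sinusoidal_encoding(30, 64)
        assert enc.shape == (30, 64)
        assert np.abs(enc).max() <= 1.0


class TestFusionGeometry:
    def test_pad_to_square_487_to_23(self):
        from vmatqa.nn.models import pad_to_square

        x = Tensor(np.ones((2, 487)))
        grid, side = pad_to_square(x)
        assert side == 23 and grid.shape == (2, 1, 23, 23)
        assert grid.data.sum() == pytest.approx(2 * 487)  # 42 zero pads

    def test_conv_stack_sizes(self):
        cfg = ModelConfig()
        from vmatqa.nn.models import ConvStack

        assert ConvStack.out_size(23, cfg) == 2 * 2 * cfg.conv_channels[-1]

    def test_avg_pool_floor(self):
        x = Tensor(np.arange(2 * 1 * 5 * 5, dtype=float).reshape(2, 1, 5, 5))
        out = avg_pool2d(x, 2)
        assert out.shape == (2, 1, 2, 2)
        assert out.data[0, 0, 0, 0] == pytest.approx((0 + 1 + 5 + 6) / 4)

    def test_max_pool1d_lengths(self):
        for L, expect in [(30, 15), (32, 16), (7, 4)]:
            x = Tensor(rng.normal(size=(1, L, 3)))
            assert max_pool1d(x).shape == (1, expect, 3)


class TestHeadsAndForward:
    def test_outputs_shapes_and_sigmoid_range(self):
        cfg = ModelConfig(**SMALL)
        for name in ("informer_cnn", "informer", "lstm", "cnn"):
            model = build_model(name, cfg)
            g, p = predict_arrays(model, make_arrays(3, W=cfg.window))
            assert g.shape == (3, 4) and p.shape == (3, 4)
            assert ((p > 0) & (p < 1)).all()

    def test_lstm_last_hidden_size(self):
        cfg = ModelConfig(**SMALL)
        model = LSTMModel(cfg)
        h = model.lstm(Tensor(make_arrays(2, W=cfg.window)["L"]))
        assert h.shape == (2, cfg.lstm_hidden)

    def test_informer_cnn_identity_conv_reproduces_informer_baseline(self):
        """The Informer baseline is exactly the fusion model with the conv
        stack replaced by the identity (weights shared)."""
        cfg = ModelConfig(**SMALL)
        ablated = InformerCNN(cfg, conv_identity=True)
        baseline = InformerModel(cfg)
        # transplant weights
        src = ablated.parameters()
        dst = baseline.parameters()
        assert set(src) == set(dst)
        for k in src:
            dst[k].data = src[k].data.copy()
        arrays = make_arrays(4, W=cfg.window, seed=9)
        g1, p1 = predict_arrays(ablated, arrays)
        g2, p2 = predict_arrays(baseline, arrays)
        np.testing.assert_allclose(g1, g2, atol=1e-7)
        np.testing.assert_allclose(p1, p2, atol=1e-7)

    def test_gradient_check_end_to_end(self):
        """Analytic gradients agree with central finite differences to 1e-4
        relative on a batch of records."""
        with default_dtype(np.float64):
            cfg = ModelConfig(**SMALL)
            model = InformerCNN(cfg)
            params = model.parameters()
            arrays = make_arrays(10, W=cfg.window, seed=4)
            r = np.random.default_rng(11)
            y = r.uniform(0.6, 1.0, size=(10, 4))
            passes = (y > 0.9).astype(float)

            def loss_value():
                g, p = model({k: Tensor(v) for k, v in arrays.items()},
                             None, False)
                return joint_loss(g, p, y, passes)

            loss = loss_value()
            model.zero_grad()
            loss.backward()
            for name in list(params)[::7]:
                p = params[name]
                idx = tuple(r.integers(0, s) for s in p.data.shape)
                eps, orig = 1e-6, p.data[idx]
                p.data[idx] = orig + eps
                lp = float(loss_value().data)
                p.data[idx] = orig - eps
                lm = float(loss_value().data)
                p.data[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = p.grad[idx]
                # absolute floor covers structurally-zero gradients (e.g. a
                # key bias, which cancels inside softmax) where the finite
                # difference is pure subtraction noise
                assert abs(fd - an) <= max(
                    1e-4 * max(abs(fd), abs(an)), 5e-10), name


class TestTraining:
    def _toy_dataset(self, n=60, W=8, seed=0):
        r = np.random.default_rng(seed)
        arrays = make_arrays(n, W=W, seed=seed)
        # labels depend linearly on one C feature: learnable signal
        signal = arrays["C"][:, 0].astype(float)
        y = np.clip(0.95 - 0.04 * signal[:, None]
                    + r.normal(0, 0.003, size=(n, 1)), 0, 1)
        y = np.repeat(y, 4, axis=1)
        return arrays, y

    def _split(self, n):
        from vmatqa.evaluation import SplitAssignment

        idx = np.arange(n)
        return SplitAssignment(train=idx[: int(0.7 * n)],
                               val=idx[int(0.7 * n): int(0.85 * n)],
                               test=idx[int(0.85 * n):], seed=0)

    def test_loss_decreases_on_learnable_data(self):
        cfg = ModelConfig(**{**SMALL, "max_epochs": 12, "patience": 12})
        arrays, y = self._toy_dataset()
        model, hist = train(arrays, y, self._split(60), cfg,
                            model_name="informer_cnn")
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_same_seed_identical_history(self):
        cfg = ModelConfig(**{**SMALL, "max_epochs": 3, "patience": 5})
        arrays, y = self._toy_dataset()
        _, h1 = train(arrays, y, self._split(60), cfg)
        _, h2 = train(arrays, y, self._split(60), cfg)
        np.testing.assert_allclose(h1["train_loss"], h2["train_loss"],
                                   rtol=1e-7)
        np.testing.assert_allclose(h1["val_loss"], h2["val_loss"], rtol=1e-7)

    def test_lr_decay_schedule(self):
        cfg = ModelConfig(**{**SMALL, "max_epochs": 45, "patience": 100})
        arrays, y = self._toy_dataset(n=20)
        _, hist = train(arrays, y, self._split(20), cfg)
        lrs = hist["lr"]
        assert lrs[0] == pytest.approx(cfg.lr)
        assert lrs[20] == pytest.approx(cfg.lr * cfg.lr_decay)
        assert lrs[40] == pytest.approx(cfg.lr * cfg.lr_decay**2)

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = ModelConfig(**{**SMALL, "max_epochs": 2, "patience": 5})
        arrays, y = self._toy_dataset()
        model, _ = train(arrays, y, self._split(60), cfg)
        g1, p1 = predict_arrays(model, arrays)
        path = tmp_path / "ckpt.pkl"
        save_checkpoint(model, path, extra={"tag": 1})
        back, extra = load_checkpoint(path)
        assert extra["tag"] == 1
        g2, p2 = predict_arrays(back, arrays)
        np.testing.assert_allclose(g1, g2, atol=1e-7)
        np.testing.assert_allclose(p1, p2, atol=1e-7)

    def test_nonfinite_loss_aborts(self):
        cfg = ModelConfig(**{**SMALL, "max_epochs": 2, "lr": 1e6})
        arrays, y = self._toy_dataset(n=20)
        with pytest.raises(FloatingPointError):
            train(arrays, y * 1e30, self._split(20), cfg)
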