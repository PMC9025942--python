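"""Network math: convolution geometry, batch norm, peephole LSTM step vs an
independent transcription, softmax properties, model construction and
end-to-end gradient correctness."""

import numpy as np
import pytest

from ecgscalonet.network import (
    ConstructionError,
    ConvBlockSpec,
    ConvGeometry,
    GeometryError,
    LSTMParams,
    ModelSpec,
    batch_norm,
    build_model,
    conv_output_shape,
    lstm_step,
    relu,
    softmax,
)


class TestConvGeometry:
    def test_same_padding_identity(self):
        geom = ConvGeometry(227, 227, 3, 3, padding=1, stride=1)
        assert conv_output_shape(geom) == (227, 227)

    def test_unit_kernel_identity(self):
        geom = ConvGeometry(13, 9, 1, 1, padding=0, stride=1)
        assert conv_output_shape(geom) == (13, 9)

    def test_stride_two(self):
        geom = ConvGeometry(4, 4, 2, 2, padding=0, stride=2)
        assert conv_output_shape(geom) == (2, 2)

    def test_matches_exhaustive_window_counting(self):
        """floor arithmetic equals enumeration of valid window placements for
        every geometry with h, w <= 12."""
        def brute(dim, f, p, s):
            count = 0
            start = -p
            while start + f <= dim + p:
                count += 1
                start += s
            return count

        for h in range(1, 13):
            for w in range(1, 13):
                for f in range(1, 6):
                    for p in range(0, 3):
                        for s in range(1, 4):
                            bh, bw = brute(h, f, p, s), brute(w, f, p, s)
                            geom = ConvGeometry(h, w, f, f, p, s)
                            if bh < 1 or bw < 1:
                                with pytest.raises(GeometryError):
                                    conv_output_shape(geom)
                            else:
                                assert conv_output_shape(geom) == (bh, bw)


class TestActivations:
    def test_relu_values(self):
        np.testing.assert_array_equal(relu(np.array([-2.0, 0.0, 5.0])),
                                      [0.0, 0.0, 5.0])
        assert relu(np.float64(-1.0)) == 0.0
        assert relu(np.float64(3.0)) == 3.0

    def test_softmax_uniform_and_sum(self, rng):
        np.testing.assert_allclose(softmax(np.zeros(3)), np.full(3, 1 / 3))
        z = rng.normal(size=(50, 3)) * 10
        p = softmax(z)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()
        np.testing.assert_array_equal(p.argmax(axis=1), z.argmax(axis=1))

    def test_softmax_shift_invariant(self, rng):
        z = rng.normal(size=(4, 3))
        np.testing.assert_allclose(softmax(z), softmax(z + 123.4), atol=1e-12)


class TestBatchNorm:
    def test_zero_variance_batch(self):
        np.testing.assert_allclose(batch_norm(np.array([2.0, 2.0, 2.0])),
                                   np.zeros(3), atol=1e-12)

    def test_hand_computed_two_point_batch(self):
        # mean 1, population variance 1 -> (0-1)/sqrt(1.001), (2-1)/sqrt(1.001)
        out = batch_norm(np.array([0.0, 2.0]), epsilon=0.001)
        np.testing.assert_allclose(out, [-0.99950037, 0.99950037], atol=1e-7)

    def test_output_mean_is_zero(self, rng):
        batch = rng.normal(5.0, 3.0, size=(16, 7))
        out = batch_norm(batch)
        assert np.abs(out.mean(axis=0)).max() <= 1e-6

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_norm(np.empty((0, 3)))


def _oracle_lstm_step(x, h_prev, c_prev, p):
    """Straight-line independent transcription of the gate equations."""
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    F = sig(x @ p.W_xf + h_prev @ p.W_hf + c_prev @ p.W_cf + p.b_f)
    i = sig(x @ p.W_xi + h_prev @ p.W_hi + c_prev @ p.W_ci + p.b_i)
    c = F * c_prev + i * np.tanh(x @ p.W_xc + h_prev @ p.W_hc + p.b_c)
    o = sig(x @ p.W_xo + h_prev @ p.W_ho + c_prev @ p.W_co + p.b_o)
    return o * np.tanh(c), c


def _random_params(rng, d, h):
    def m(shape):
        return rng.normal(size=shape)
    return LSTMParams(
        W_xf=m((d, h)), W_hf=m((h, h)), W_cf=m((h, h)), b_f=m(h),
        W_xi=m((d, h)), W_hi=m((h, h)), W_ci=m((h, h)), b_i=m(h),
        W_xc=m((d, h)), W_hc=m((h, h)), b_c=m(h),
        W_xo=m((d, h)), W_ho=m((h, h)), W_co=m((h, h)), b_o=m(h),
    )


class TestLSTMStep:
    def test_all_zero_weights_and_state(self):
        d, h = 3, 4
        zeros = LSTMParams(**{
            f: np.zeros((d, h)) if f.startswith("W_x")
            else np.zeros((h, h)) if f.startswith(("W_h", "W_c"))
            else np.zeros(h)
            for f in LSTMParams.__dataclass_fields__
        })
        h_t, c_t = lstm_step(np.ones(d), np.zeros(h), np.zeros(h), zeros)
        np.testing.assert_allclose(c_t, 0.0)
        np.testing.assert_allclose(h_t, 0.0)

    def test_zero_weights_nonzero_cell(self):
        """With zero weights, gates are all 0.5: c_t = c/2, h_t = tanh(c/2)/2."""
        d, h = 2, 3
        zeros = LSTMParams(**{
            f: np.zeros((d, h)) if f.startswith("W_x")
            else np.zeros((h, h)) if f.startswith(("W_h", "W_c"))
            else np.zeros(h)
            for f in LSTMParams.__dataclass_fields__
        })
        c = np.array([0.4, -1.0, 2.0])
        h_t, c_t = lstm_step(np.zeros(d), np.zeros(h), c, zeros)
        np.testing.assert_allclose(c_t, 0.5 * c, atol=1e-15)
        np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * c), atol=1e-15)

    def test_matches_transcription_oracle_on_100_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            d = int(rng.integers(1, 6))
            h = int(rng.integers(1, 6))
            p = _random_params(rng, d, h)
            x = rng.normal(size=d)
            hp = rng.normal(size=h)
            cp = rng.normal(size=h)
            got_h, got_c = lstm_step(x, hp, cp, p)
            exp_h, exp_c = _oracle_lstm_step(x, hp, cp, p)
            np.testing.assert_allclose(got_h, exp_h, atol=1e-10)
            np.testing.assert_allclose(got_c, exp_c, atol=1e-10)
            assert np.all(np.abs(got_h) < 1.0)

    def test_shape_mismatch_rejected(self, rng):
        p = _random_params(rng, 3, 4)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(5), np.zeros(4), np.zeros(4), p)


def _tiny_spec(dropout=0.0):
    return ModelSpec(
        input_shape=(12, 12, 3),
        conv_blocks=(ConvBlockSpec(4, norm="cross_channel"),
                     ConvBlockSpec(5, norm="batch")),
        lstm_hidden_units=6, fc_sizes=(7,), dropout_rate=dropout,
    )


class TestBuildModel:
    def test_forward_emits_probability_rows(self, rng):
        model = build_model(_tiny_spec(), seed=0)
        x = rng.normal(size=(2, 12, 12, 3))
        probs = softmax(model.forward(x))
        assert probs.shape == (2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_eval_forward_is_deterministic_even_with_dropout(self, rng):
        model = build_model(_tiny_spec(dropout=0.5), seed=0)
        x = rng.normal(size=(2, 12, 12, 3))
        np.testing.assert_array_equal(model.forward(x, train=False),
                                      model.forward(x, train=False))

    def test_parameter_count_matches_closed_form(self):
        """Reduced spec: 1 conv block (8 filters), hidden 4; counted by hand."""
        spec = ModelSpec(
            input_shape=(16, 16, 3),
            conv_blocks=(ConvBlockSpec(8, kernel=3, norm="batch"),),
            lstm_hidden_units=4, fc_sizes=(5,), dropout_rate=0.0,
        )
        model = build_model(spec, seed=0)
        conv = 3 * 3 * 3 * 8 + 8
        bn = 8 + 8
        d = (16 // 2) * 8  # feature-map width x channels after pooling
        lstm = 4 * (d * 4) + 4 * (4 * 4) + 3 * (4 * 4) + 4 * 4
        fc = (4 * 5 + 5) + (5 * 3 + 3)
        assert model.n_params == conv + bn + lstm + fc

    def test_impossible_geometry_names_layer(self):
        spec = ModelSpec(
            input_shape=(4, 4, 3),
            conv_blocks=(ConvBlockSpec(4), ConvBlockSpec(4), ConvBlockSpec(4)),
        )
        with pytest.raises(ConstructionError, match="conv block 3"):
            build_model(spec, seed=0)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        from ecgscalonet.network import Model
        model = build_model(_tiny_spec(), seed=3)
        x = rng.normal(size=(2, 12, 12, 3))
        before = model.forward(x)
        model.save(tmp_path / "ckpt.npz")
        loaded = Model.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(loaded.forward(x), before)


class TestGradients:
    def test_backward_matches_numeric_gradients(self, rng):
        """Central-difference check through the full conv/LRN/BN/pool/LSTM/FC
        stack on a handful of sampled parameters."""
        model = build_model(_tiny_spec(), seed=0)
        for _, layer, name in model.parameters():
            layer.params[name] = layer.params[name].astype(np.float64)
        x = rng.normal(size=(3, 12, 12, 3))
        r = np.eye(3)[rng.integers(0, 3, size=3)]

        from ecgscalonet.training import loss_and_grad

        def loss():
            return loss_and_grad(model.forward(x, train=True), r)[0]

        logits = model.forward(x, train=True)
        _, dlogits = loss_and_grad(logits, r)
        model.backward(dlogits)
        analytic = {k: l.grads[n].copy() for k, l, n in model.parameters()}

        eps = 1e-6
        for key, layer, name in model.parameters():
            p = layer.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                got = analytic[key][idx]
                assert abs(num - got) <= 1e-4 * max(1.0, abs(num)), (key, idx)
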