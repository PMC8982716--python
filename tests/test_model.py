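"""Network core: cell recurrence, dilated forward pass, head,
parameter accounting and checkpointing."""

import numpy as np
import pytest

from cgmdrnn.model import (
    CellParams,
    DRNNModel,
    dilated_forward,
    forward_states,
    load_checkpoint,
    loss_and_grads,
    param_count,
    predict,
    save_checkpoint,
    vanilla_step,
)


def random_model(dilations, hidden=3, inputs=4, seed=0):
    m = DRNNModel.init(input_size=inputs, hidden_size=hidden,
                       dilations=dilations, seed=seed)
    rng = np.random.default_rng(seed + 100)
    m.head_w[:] = rng.standard_normal(hidden)
    m.head_b[:] = rng.standard_normal(1)
    return m


class TestVanillaStep:
    def test_zero_weights_zero_output(self, rng):
        cell = CellParams(np.zeros((3, 3)), np.zeros((3, 4)), np.zeros(3))
        h = vanilla_step(cell, rng.standard_normal(3), rng.standard_normal(4))
        np.testing.assert_array_equal(h, 0.0)

    def test_scalar_case(self):
        cell = CellParams(np.zeros((1, 1)), np.ones((1, 1)), np.zeros(1))
        h = vanilla_step(cell, np.zeros(1), np.array([0.5]))
        assert h[0] == pytest.approx(np.tanh(0.5), abs=1e-12)
        assert h[0] == pytest.approx(0.46212, abs=5e-6)

    def test_output_inside_unit_interval(self, rng):
        cell = CellParams(
            rng.standard_normal((5, 5)),
            rng.standard_normal((5, 4)),
            rng.standard_normal(5),
        )
        h = vanilla_step(cell, rng.standard_normal(5), rng.standard_normal(4))
        assert np.abs(h).max() < 1.0

    def test_shape_mismatch(self, rng):
        cell = CellParams(np.zeros((3, 3)), np.zeros((3, 4)), np.zeros(3))
        with pytest.raises(ValueError, match="shape"):
            vanilla_step(cell, rng.standard_normal(2), rng.standard_normal(4))


def stacked_rnn_oracle(model, window):
    """Plain stacked RNN (all dilations 1), independent per-step loop."""
    h_layers = [np.zeros(c.hidden_size) for c in model.layers]
    for t in range(window.shape[0]):
        inp = window[t]
        for i, cell in enumerate(model.layers):
            h_layers[i] = np.tanh(
                cell.W_rec @ h_layers[i] + cell.W_in @ inp + cell.b
            )
            inp = h_layers[i]
    return h_layers[-1]


class TestDilatedForward:
    def test_equals_stacked_rnn_when_dilation_one(self, rng):
        """Unit dilations reduce the network to a plain stacked RNN."""
        for seed in range(10):
            m = random_model((1, 1, 1), hidden=4, seed=seed)
            w = rng.standard_normal((9, 4))
            np.testing.assert_allclose(
                dilated_forward(m, w), stacked_rnn_oracle(m, w), atol=1e-12
            )

    def test_zero_weights(self):
        m = DRNNModel.init(hidden_size=4, dilations=(1, 2, 4), seed=0)
        for c in m.layers:
            c.W_rec[:] = 0
            c.W_in[:] = 0
        h = dilated_forward(m, np.ones((12, 4)))
        np.testing.assert_array_equal(h, 0.0)

    def test_dilated_recurrence_skips_steps(self):
        """A layer with dilation d at step t sees its own state from t-d."""
        m = DRNNModel.init(input_size=1, hidden_size=1, dilations=(2,), seed=0)
        cell = m.layers[0]
        cell.W_rec[:] = 0.5
        cell.W_in[:] = 1.0
        cell.b[:] = 0.0
        x = np.array([[1.0], [2.0], [0.5], [0.25]])
        h = forward_states(m, x[None])[0][0, :, 0]
        expect = [np.tanh(1.0), np.tanh(2.0)]
        expect.append(np.tanh(0.5 * expect[0] + 0.5))
        expect.append(np.tanh(0.5 * expect[1] + 0.25))
        np.testing.assert_allclose(h, expect, atol=1e-12)

    def test_receptive_field_spans_window(self, rng):
        """Perturbing the first input changes the final top state."""
        m = random_model((1, 2, 4), hidden=8, seed=3)
        w = rng.standard_normal((12, 4))
        h0 = dilated_forward(m, w)
        w2 = w.copy()
        w2[0, 0] += 1e-3
        h1 = dilated_forward(m, w2)
        assert np.abs(h1 - h0).max() > 0

    def test_requires_positive_length(self):
        m = DRNNModel.init(seed=0)
        with pytest.raises(ValueError):
            forward_states(m, np.empty((1, 0, 4)))


class TestPredictHead:
    def test_zero_head_is_persistence(self, rng):
        m = DRNNModel.init(seed=0)  # head initialised to zero
        h = rng.standard_normal(32)
        assert predict(m, h, 137.0) == pytest.approx(137.0)

    def test_delta_plus_current(self):
        m = DRNNModel.init(hidden_size=2, seed=0)
        m.head_w[:] = 0.0
        m.head_b[:] = 10.0
        assert predict(m, np.zeros(2), 100.0) == pytest.approx(110.0)

    def test_delta_identity(self, rng):
        m = random_model((1, 2), hidden=5)
        h = rng.standard_normal(5)
        delta = predict(m, h, 0.0)
        assert predict(m, h, 88.0) - 88.0 == pytest.approx(delta, abs=1e-10)


class TestParamCount:
    @pytest.mark.parametrize(
        "cell,n,m,expect",
        [("vanilla", 32, 4, 1184), ("lstm", 32, 4, 4 * 1184), ("gru", 32, 4, 3 * 1184)],
    )
    def test_formulas(self, cell, n, m, expect):
        assert param_count(cell, n, m) == expect

    @pytest.mark.parametrize("n,m", [(8, 3), (32, 4), (64, 32)])
    def test_lstm_gru_ratios(self, n, m):
        v = param_count("vanilla", n, m)
        assert param_count("lstm", n, m) == 4 * v
        assert param_count("gru", n, m) == 3 * v

    def test_unknown_cell(self):
        with pytest.raises(ValueError):
            param_count("mgu", 8, 4)

    def test_default_model_total(self):
        """Stored-array total equals the per-layer formula sum + head."""
        m = DRNNModel.init()
        expect = (
            param_count("vanilla", 32, 4)
            + 2 * param_count("vanilla", 32, 32)
            + 32 + 1
        )
        assert m.n_params() == expect


def test_gradients_match_finite_differences(rng):
    """Analytic BPTT vs central differences on a 2-unit, 3-step model."""
    m = random_model((1, 2), hidden=2, inputs=3, seed=7)
    X = rng.standard_normal((4, 3, 3))
    y = rng.standard_normal(4)
    _, grads = loss_and_grads(m, X, y)
    eps = 1e-6
    for k, p in m.params().items():
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p[i]
            p[i] = orig + eps
            lp, _ = loss_and_grads(m, X, y)
            p[i] = orig - eps
            lm, _ = loss_and_grads(m, X, y)
            p[i] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(grads[k][i]), 1e-8)
            assert abs(num - grads[k][i]) / denom < 1e-4, k


def test_checkpoint_round_trip(tmp_path):
    m = random_model((1, 2, 4), hidden=6)
    path = str(tmp_path / "ckpt")
    save_checkpoint(m, path, manifest_extra={"seed": 1})
    back, manifest = load_checkpoint(path)
    assert manifest["dilations"] == [1, 2, 4]
    assert manifest["seed"] == 1
    for k, v in m.params().items():
        np.testing.assert_array_equal(back.params()[k], v)
    w = np.random.default_rng(0).standard_normal((8, 4))
    np.testing.assert_array_equal(dilated_forward(back, w), dilated_forward(m, w))
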