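"""ConvLSTM network: cell equations, gradients, loss, forward regression."""

import json
from pathlib import Path

import numpy as np
import pytest

from rt4dcbct.network import (
    ConvLSTMCellParams,
    ConvLSTMRegressor,
    ConvLSTMState,
    NetworkConfig,
    convlstm_cell_step,
    weighted_loss,
)
from rt4dcbct.network.training import _loss_and_grad

DATA = Path(__file__).parent / "data"


def scalar_lstm_step(x, h, c, w):
    """Independent scalar LSTM oracle (plain Python floats)."""
    import math

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    i = sig(w["wxi"] * x + w["whi"] * h + w["bi"])
    f = sig(w["wxf"] * x + w["whf"] * h + w["bf"])
    o = sig(w["wxo"] * x + w["who"] * h + w["bo"])
    g = math.tanh(w["wxg"] * x + w["whg"] * h + w["bg"])
    c_new = f * c + i * g
    h_new = o * math.tanh(c_new)
    return h_new, c_new


def cell_params_from_scalars(w):
    """Embed scalar weights as the centre taps of 3x3 kernels (h = 1, c_in = 1)."""
    Wx = np.zeros((4, 1, 3, 3))
    Wh = np.zeros((4, 1, 3, 3))
    b = np.zeros(4)
    for row, (kx, kh, kb) in enumerate(
        [("wxi", "whi", "bi"), ("wxf", "whf", "bf"),
         ("wxo", "who", "bo"), ("wxg", "whg", "bg")]
    ):
        Wx[row, 0, 1, 1] = w[kx]
        Wh[row, 0, 1, 1] = w[kh]
        b[row] = w[kb]
    return ConvLSTMCellParams(Wx=Wx, Wh=Wh, b=b)


class TestCellStep:
    def test_zero_parameters_keep_state_zero(self):
        params = ConvLSTMCellParams(
            Wx=np.zeros((4, 1, 3, 3)), Wh=np.zeros((4, 1, 3, 3)), b=np.zeros(4)
        )
        state = None
        for _ in range(5):
            state = convlstm_cell_step(np.ones((1, 4, 4, 1)), state, params)
            # sigma(0) = 0.5, tanh(0) = 0 => G_t = 0 so C stays 0 and H stays 0
            assert np.all(state.C == 0.0)
            assert np.all(state.H == 0.0)

    def test_matches_scalar_lstm_oracle(self, rng):
        """On a 1x1 grid with same padding only the centre tap acts, so the
        cell must reproduce a hand-written scalar LSTM to 1e-10."""
        keys = ["wxi", "whi", "bi", "wxf", "whf", "bf",
                "wxo", "who", "bo", "wxg", "whg", "bg"]
        w = {k: float(v) for k, v in zip(keys, rng.normal(size=12))}
        params = cell_params_from_scalars(w)
        xs = rng.normal(size=6)
        h = c = 0.0
        state = None
        for x in xs:
            X = np.full((1, 1, 1, 1), x)
            state = convlstm_cell_step(X, state, params)
            h, c = scalar_lstm_step(float(x), h, c, w)
            assert abs(state.H[0, 0, 0, 0] - h) < 1e-10
            assert abs(state.C[0, 0, 0, 0] - c) < 1e-10

    def test_gates_bounded(self, rng):
        """H stays inside (-1, 1) and C finite over many random steps."""
        h = 3
        params = ConvLSTMCellParams(
            Wx=rng.normal(size=(4 * h, 2, 3, 3)),
            Wh=rng.normal(size=(4 * h, h, 3, 3)),
            b=rng.normal(size=4 * h),
        )
        state = None
        for _ in range(50):
            X = rng.normal(size=(2, 5, 5, 2)) * 3.0
            state = convlstm_cell_step(X, state, params)
            assert np.all(np.abs(state.H) < 1.0)
            assert np.all(np.isfinite(state.C))

    def test_shape_mismatch_rejected(self, rng):
        params = ConvLSTMCellParams(
            Wx=np.zeros((4, 1, 3, 3)), Wh=np.zeros((4, 1, 3, 3)), b=np.zeros(4)
        )
        with pytest.raises(ValueError):
            convlstm_cell_step(np.zeros((1, 4, 4, 2)), None, params)
        bad_state = ConvLSTMState.zeros(1, 6, 6, 1)
        with pytest.raises(ValueError):
            convlstm_cell_step(np.zeros((1, 4, 4, 1)), bad_state, params)

    def test_kernel_size_enforced(self):
        with pytest.raises(ValueError):
            ConvLSTMCellParams(
                Wx=np.zeros((4, 1, 5, 5)), Wh=np.zeros((4, 1, 5, 5)), b=np.zeros(4)
            )


class TestForward:
    def make_net(self, **kw):
        defaults = dict(hidden_channels=2, cell_layers=2, sequence_length=3,
                        pooling="conv", fc_hidden=6, k=3)
        defaults.update(kw)
        return ConvLSTMRegressor(
            NetworkConfig(**defaults), input_shape=(8, 8), seed=5, dtype=np.float64
        )

    def test_deterministic(self, rng):
        net = self.make_net()
        x = rng.normal(size=(2, 3, 8, 8, 1))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_distinct_inputs_distinct_outputs(self):
        net = self.make_net()
        y0 = net.forward(np.zeros((1, 3, 8, 8, 1)))
        y1 = net.forward(np.ones((1, 3, 8, 8, 1)))
        assert not np.allclose(y0, y1)

    def test_wrong_sequence_length_rejected(self, rng):
        net = self.make_net()
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(1, 5, 8, 8, 1)))

    def test_frozen_fixture(self):
        """Forward pass reproduces the stored regression fixture to 1e-6."""
        blob = json.loads((DATA / "convlstm_golden.json").read_text())
        net = ConvLSTMRegressor(
            NetworkConfig(**blob["config"]),
            input_shape=tuple(blob["input_shape"]),
            seed=blob["seed"],
            dtype=np.float64,
        )
        for k, v in blob["params"].items():
            np.testing.assert_allclose(net.params[k], np.asarray(v), atol=1e-12)
        y = net.forward(np.asarray(blob["input"]))
        np.testing.assert_allclose(y, np.asarray(blob["output"]), atol=1e-6)

    @pytest.mark.parametrize("pooling", ["conv", "max", "avg", "none"])
    def test_gradients_match_finite_differences(self, pooling, rng):
        net = ConvLSTMRegressor(
            NetworkConfig(hidden_channels=2, cell_layers=2, sequence_length=2,
                          pooling=pooling, fc_hidden=5, k=2),
            input_shape=(6, 6), seed=3, dtype=np.float64,
        )
        x = rng.normal(size=(2, 2, 6, 6, 1))
        y = rng.normal(size=(2, 2))
        w = np.array([2.0 / 3.0, 1.0 / 3.0])

        def loss():
            yh, cache = net.forward(x, want_cache=True)
            l, dy = _loss_and_grad(y, yh, w)
            return l, cache, dy

        _, cache, dy = loss()
        grads = net.backward(cache, dy)
        for name, p in net.params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, old = 1e-6, p[idx]
                p[idx] = old + eps
                lp, _, _ = loss()
                p[idx] = old - eps
                lm, _, _ = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name][idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num) + abs(ana)), name


class TestWeightedLoss:
    def test_zero_for_perfect_prediction(self, rng):
        y = rng.normal(size=(4, 3))
        assert weighted_loss(y, y, (2 / 6, 1 / 6, 1 / 6)) == 0.0

    def test_hand_value(self):
        """Residual (3,3,3) under weights (2/6,1/6,1/6): ||(1, .5, .5)||^2 = 1.5."""
        y = np.array([[3.0, 3.0, 3.0]])
        y_hat = np.zeros((1, 3))
        assert weighted_loss(y, y_hat, (2 / 6, 1 / 6, 1 / 6)) == pytest.approx(1.5)

    def test_quadratic_homogeneity(self, rng):
        y = rng.normal(size=(5, 3))
        y_hat = rng.normal(size=(5, 3))
        w = (2 / 6, 1 / 6, 1 / 6)
        l1 = weighted_loss(y, y_hat, w)
        l2 = weighted_loss(y, 2 * y_hat - y, w)   # doubles every residual
        assert l2 == pytest.approx(4.0 * l1)

    def test_weight_length_mismatch_rejected(self, rng):
        y = rng.normal(size=(2, 3))
        with pytest.raises(ValueError):
            weighted_loss(y, y, (0.5, 0.5))
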