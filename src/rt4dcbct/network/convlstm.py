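"""ConvLSTM cell and the stacked sequence-regression network.

Cell update (all products of kernels with maps are 3x3 convolutions, ``o``
is the Hadamard product)::

    i_t = sigmoid(W_xi * X_t + W_hi * H_{t-1} + b_i)
    f_t = sigmoid(W_xf * X_t + W_hf * H_{t-1} + b_f)
    o_t = sigmoid(W_xo * X_t + W_ho * H_{t-1} + b_o)
    G_t = tanh   (W_xg * X_t + W_hg * H_{t-1} + b_g)
    C_t = f_t o C_{t-1} + i_t o G_t
    H_t = o_t o tanh(C_t)

The regression head takes the final hidden map of the top cell layer
through one 2x down-sampling pooling stage (a learned strided convolution
by default) and two fully connected layers of width 1024 and k.

Recurrence requires shape-preserving convolutions, so the gate convolutions
use "same" zero padding; the head's pooling convolution is unpadded.
Feature maps are channels-last ``(B, H, W, C)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ops import (
    conv2d_pool,
    conv2d_pool_backward,
    conv_from_cols,
    conv_weight_grad,
    flip_kernel_matrix,
    im2col_same,
    kernel_matrix,
    pool2x2,
    pool2x2_backward,
    sigmoid,
)

_GATES = 4  # i, f, o, g


@dataclass
class ConvLSTMCellParams:
    """Stacked gate kernels for one cell layer.

    ``Wx`` stacks (W_xi, W_xf, W_xo, W_xg) along the output-channel axis into
    a single ``(4h, C_in, 3, 3)`` kernel (one convolution instead of four);
    ``Wh`` does the same for the hidden-to-hidden kernels and ``b`` for the
    biases.
    """

    Wx: np.ndarray   # (4h, c_in, 3, 3)
    Wh: np.ndarray   # (4h, h, 3, 3)
    b: np.ndarray    # (4h,)

    def __post_init__(self) -> None:
        h4 = self.Wx.shape[0]
        if h4 % _GATES != 0:
            raise ValueError("gate kernel count must be a multiple of 4")
        if self.Wh.shape[0] != h4 or self.Wh.shape[1] != h4 // _GATES:
            raise ValueError("inconsistent hidden-kernel shape")
        if self.Wx.shape[2:] != (3, 3) or self.Wh.shape[2:] != (3, 3):
            raise ValueError("kernel size must be 3")
        if self.b.shape != (h4,):
            raise ValueError("bias shape mismatch")

    @property
    def hidden_channels(self) -> int:
        return self.Wx.shape[0] // _GATES


@dataclass
class ConvLSTMState:
    """Hidden map H_t and cell memory map C_t of one layer, (B, H, W, h)."""

    H: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        if self.H.shape != self.C.shape:
            raise ValueError("H and C must share one shape")

    @classmethod
    def zeros(cls, batch: int, height: int, width: int, hidden: int,
              dtype=np.float32) -> "ConvLSTMState":
        z = np.zeros((batch, height, width, hidden), dtype=dtype)
        return cls(H=z.copy(), C=z)


class _LayerMats:
    """Cached GEMM forms of one layer's kernels for a forward/backward pass."""

    def __init__(self, p: ConvLSTMCellParams):
        self.p = p
        self.Wxm = kernel_matrix(p.Wx)
        self.Whm = kernel_matrix(p.Wh)
        self.Wxm_flip = None
        self.Whm_flip = None

    def flips(self):
        if self.Wxm_flip is None:
            self.Wxm_flip = flip_kernel_matrix(self.p.Wx)
            self.Whm_flip = flip_kernel_matrix(self.p.Wh)
        return self.Wxm_flip, self.Whm_flip


def _cell_forward(X, H_prev, C_prev, mats: _LayerMats):
    """One cell step; returns (H, C, cache-for-backward)."""
    h = mats.p.hidden_channels
    cols_x = im2col_same(X)
    cols_h = im2col_same(H_prev)
    a = conv_from_cols(cols_x, mats.Wxm) + conv_from_cols(cols_h, mats.Whm)
    a += mats.p.b
    i = sigmoid(a[..., 0 * h : 1 * h])
    f = sigmoid(a[..., 1 * h : 2 * h])
    o = sigmoid(a[..., 2 * h : 3 * h])
    g = np.tanh(a[..., 3 * h : 4 * h])
    C = f * C_prev + i * g
    tC = np.tanh(C)
    H = o * tC
    cache = (cols_x, cols_h, C_prev, i, f, o, g, tC)
    return H, C, cache


def convlstm_cell_step(
    X_t: np.ndarray, state: ConvLSTMState | None, params: ConvLSTMCellParams
) -> ConvLSTMState:
    """Apply one ConvLSTM cell update; zero initial state when unset.

    ``X_t`` is a channels-last feature map (B, H, W, C_in).
    """
    X_t = np.asarray(X_t)
    if X_t.ndim != 4:
        raise ValueError("X_t must be (B, H, W, C)")
    if X_t.shape[-1] != params.Wx.shape[1]:
        raise ValueError(
            f"input has {X_t.shape[-1]} channels, kernels expect {params.Wx.shape[1]}"
        )
    if state is None:
        state = ConvLSTMState.zeros(
            X_t.shape[0], X_t.shape[1], X_t.shape[2], params.hidden_channels,
            dtype=X_t.dtype,
        )
    if state.H.shape[1:3] != X_t.shape[1:3]:
        raise ValueError("state and input spatial shapes differ")
    H, C, _ = _cell_forward(X_t, state.H, state.C, _LayerMats(params))
    return ConvLSTMState(H=H, C=C)


def _cell_backward(dH, dC, cache, mats: _LayerMats):
    """Backward through one cell step.

    Returns (dX, dH_prev, dC_prev, dWx, dWh, db); dH/dC are the gradients
    flowing into H_t and C_t.
    """
    cols_x, cols_h, C_prev, i, f, o, g, tC = cache
    do = dH * tC
    dC_total = dC + dH * o * (1.0 - tC * tC)
    df = dC_total * C_prev
    di = dC_total * g
    dg = dC_total * i
    dC_prev = dC_total * f
    da = np.concatenate(
        [
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            do * o * (1.0 - o),
            dg * (1.0 - g * g),
        ],
        axis=-1,
    )
    cin = cols_x.shape[-1] // 9
    h = mats.p.hidden_channels
    dWx = conv_weight_grad(cols_x, da, cin)
    dWh = conv_weight_grad(cols_h, da, h)
    db = da.sum(axis=(0, 1, 2))
    Wxm_flip, Whm_flip = mats.flips()
    cols_da = im2col_same(da)
    dX = conv_from_cols(cols_da, Wxm_flip)
    dH_prev = conv_from_cols(cols_da, Whm_flip)
    return dX, dH_prev, dC_prev, dWx, dWh, db


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the ConvLSTM regressor.

    ``hidden_channels`` is the per-layer gate feature count (the ablation
    optimum at full scale is 40) and ``cell_layers`` the number of stacked
    ConvLSTM layers (optimum 2).  ``pooling`` selects the head's 2x
    down-sampling stage: learned strided convolution (default, the best
    converging choice), max, average, or none.
    """

    hidden_channels: int = 40
    cell_layers: int = 2
    sequence_length: int = 4
    pooling: str = "conv"          # conv | max | avg | none
    fc_hidden: int = 1024
    k: int = 3

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.pooling not in ("conv", "max", "avg", "none"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.hidden_channels < 1 or self.cell_layers < 1:
            raise ValueError("hidden_channels and cell_layers must be >= 1")


class ConvLSTMRegressor:
    """Stacked ConvLSTM layers + convolutional-pooling regression head."""

    def __init__(
        self,
        config: NetworkConfig,
        input_shape: tuple[int, int],
        in_channels: int = 1,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        self.config = config
        self.input_shape = tuple(input_shape)
        self.in_channels = in_channels
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(seed)

    # -- initialisation ----------------------------------------------------
    def _init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        h = self.config.hidden_channels
        c_in = self.in_channels
        dt = self.dtype

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape).astype(dt)

        for l in range(self.config.cell_layers):
            cin = c_in if l == 0 else h
            self.params[f"cell{l}_Wx"] = glorot((4 * h, cin, 3, 3), cin * 9, h * 9)
            self.params[f"cell{l}_Wh"] = glorot((4 * h, h, 3, 3), h * 9, h * 9)
            b = np.zeros(4 * h, dtype=dt)
            b[h : 2 * h] = 1.0            # forget-gate bias starts open
            self.params[f"cell{l}_b"] = b

        Hh, Ww = self.input_shape
        if self.config.pooling == "conv":
            self.params["head_Wc"] = glorot((h, h, 3, 3), h * 9, h * 9)
            self.params["head_bc"] = np.zeros(h, dtype=dt)
            Ho, Wo = (Hh - 3) // 2 + 1, (Ww - 3) // 2 + 1
        elif self.config.pooling == "none":
            Ho, Wo = Hh, Ww
        else:
            Ho, Wo = Hh // 2, Ww // 2
        feat = h * Ho * Wo
        self._head_spatial = (Ho, Wo)
        self.params["fc1_W"] = glorot((feat, self.config.fc_hidden), feat,
                                      self.config.fc_hidden)
        self.params["fc1_b"] = np.zeros(self.config.fc_hidden, dtype=dt)
        self.params["fc2_W"] = glorot((self.config.fc_hidden, self.config.k),
                                      self.config.fc_hidden, self.config.k)
        self.params["fc2_b"] = np.zeros(self.config.k, dtype=dt)

    def cell_params(self, layer: int) -> ConvLSTMCellParams:
        return ConvLSTMCellParams(
            Wx=self.params[f"cell{layer}_Wx"],
            Wh=self.params[f"cell{layer}_Wh"],
            b=self.params[f"cell{layer}_b"],
        )

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Regress k coefficients from a (B, T, H, W, C) DRR sequence."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 4:                     # (T, H, W, C) single sequence
            x = x[None]
        B, T, Hh, Ww, C = x.shape
        cfg = self.config
        if T != cfg.sequence_length:
            raise ValueError(f"expected T={cfg.sequence_length}, got {T}")
        if (Hh, Ww) != self.input_shape or C != self.in_channels:
            raise ValueError("input shape does not match the network")

        layer_caches = []
        layer_mats = [_LayerMats(self.cell_params(l)) for l in range(cfg.cell_layers)]
        seq = [x[:, t] for t in range(T)]
        for l in range(cfg.cell_layers):
            mats = layer_mats[l]
            H = np.zeros((B, Hh, Ww, cfg.hidden_channels), dtype=self.dtype)
            Cm = np.zeros_like(H)
            caches_t = []
            outputs = []
            for t in range(T):
                H, Cm, cache = _cell_forward(seq[t], H, Cm, mats)
                caches_t.append(cache)
                outputs.append(H)
            layer_caches.append(caches_t)
            seq = outputs

        z = seq[-1]                         # final hidden map of the top layer
        head_cache = {"z": z}
        if cfg.pooling == "conv":
            pmap = conv2d_pool(z, self.params["head_Wc"], self.params["head_bc"])
        elif cfg.pooling == "none":
            pmap = z
        else:
            pmap, arg = pool2x2(z, cfg.pooling)
            head_cache["arg"] = arg
        flat = pmap.reshape(B, -1)
        a1 = flat @ self.params["fc1_W"] + self.params["fc1_b"]
        r1 = np.maximum(a1, 0.0)
        y = r1 @ self.params["fc2_W"] + self.params["fc2_b"]
        if not want_cache:
            return y
        head_cache.update({"pmap_shape": pmap.shape, "flat": flat, "a1": a1, "r1": r1})
        return y, {
            "layers": layer_caches,
            "mats": layer_mats,
            "head": head_cache,
            "B": B,
            "T": T,
        }

    # -- backward ----------------------------------------------------------
    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss with upstream dL/dy, for all parameters."""
        cfg = self.config
        B, T = cache["B"], cache["T"]
        hc = cache["head"]
        grads: dict[str, np.ndarray] = {}

        dy = dy.astype(self.dtype)
        dr1 = dy @ self.params["fc2_W"].T
        grads["fc2_W"] = hc["r1"].T @ dy
        grads["fc2_b"] = dy.sum(axis=0)
        da1 = dr1 * (hc["a1"] > 0)
        grads["fc1_W"] = hc["flat"].T @ da1
        grads["fc1_b"] = da1.sum(axis=0)
        dflat = da1 @ self.params["fc1_W"].T
        dpmap = dflat.reshape(hc["pmap_shape"])

        z = hc["z"]
        if cfg.pooling == "conv":
            dz, dWc, dbc = conv2d_pool_backward(z, self.params["head_Wc"], dpmap)
            grads["head_Wc"] = dWc
            grads["head_bc"] = dbc
        elif cfg.pooling == "none":
            dz = dpmap
        else:
            dz = pool2x2_backward(z.shape, dpmap, cfg.pooling, hc.get("arg"))

        # BPTT, top layer first; dX of layer l feeds dH_ext of layer l-1
        dH_ext = [np.zeros_like(z) for _ in range(T)]
        dH_ext[T - 1] = dz
        for l in range(cfg.cell_layers - 1, -1, -1):
            mats = cache["mats"][l]
            caches_t = cache["layers"][l]
            p = mats.p
            dWx = np.zeros_like(p.Wx)
            dWh = np.zeros_like(p.Wh)
            db = np.zeros_like(p.b)
            dH_next = np.zeros_like(dH_ext[T - 1])
            dC_next = np.zeros_like(dH_next)
            dX_seq = []
            for t in range(T - 1, -1, -1):
                dH = dH_ext[t] + dH_next
                dX, dH_next, dC_next, dWx_t, dWh_t, db_t = _cell_backward(
                    dH, dC_next, caches_t[t], mats
                )
                dWx += dWx_t
                dWh += dWh_t
                db += db_t
                dX_seq.append(dX)
            grads[f"cell{l}_Wx"] = dWx
            grads[f"cell{l}_Wh"] = dWh
            grads[f"cell{l}_b"] = db
            dH_ext = dX_seq[::-1]
        return grads
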