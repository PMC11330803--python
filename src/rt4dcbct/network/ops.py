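"""Array primitives for the ConvLSTM network: convolutions, pooling, dense
layers and ADAM.  Every forward function has a matching backward; gradients
are validated against finite differences in the test suite.

Layout conventions: feature maps are channels-last ``(B, H, W, C)`` (patch
extraction then reduces to contiguous slice copies and the convolution to a
single GEMM); 3x3 convolution kernels are ``(C_out, C_in, 3, 3)`` with
stride 1 and "same" zero padding (the recurrent path must preserve spatial
shape).  The head's convolutional pooling uses stride 2 with no padding.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid  # numerically stable logistic

__all__ = [
    "sigmoid",
    "im2col_same",
    "kernel_matrix",
    "conv2d_same",
    "conv2d_same_backward",
    "conv2d_pool",
    "conv2d_pool_backward",
    "pool2x2",
    "pool2x2_backward",
    "Adam",
]


def im2col_same(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B, H, W, 9C) patch tensor for a same-padded 3x3 conv.

    Column blocks are ordered (u, v, c) to match `kernel_matrix`.
    """
    B, H, W, C = x.shape
    xp = np.zeros((B, H + 2, W + 2, C), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # (B, H, W, C, 3, 3) -> (B, H, W, 3, 3, C); the reshape makes the copy
    return v.transpose(0, 1, 2, 4, 5, 3).reshape(B, H, W, 9 * C)


def kernel_matrix(W: np.ndarray) -> np.ndarray:
    """(C_out, C_in, 3, 3) kernel -> (9*C_in, C_out) GEMM matrix."""
    Cout, Cin = W.shape[:2]
    return np.ascontiguousarray(
        W.transpose(2, 3, 1, 0).reshape(9 * Cin, Cout)
    )


def matrix_kernel(Wm: np.ndarray, c_in: int) -> np.ndarray:
    """Inverse of `kernel_matrix`."""
    Cout = Wm.shape[1]
    return np.ascontiguousarray(
        Wm.reshape(3, 3, c_in, Cout).transpose(3, 2, 0, 1)
    )


def conv2d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 same-padded 3x3 convolution (cross-correlation), channels-last."""
    B, H, Wd, C = x.shape
    cols = im2col_same(x)
    y = cols.reshape(B * H * Wd, 9 * C) @ kernel_matrix(W)
    y = y.reshape(B, H, Wd, W.shape[0])
    if b is not None:
        y += b
    return y


def conv_from_cols(cols: np.ndarray, Wm: np.ndarray) -> np.ndarray:
    """GEMM part of the convolution given a precomputed patch tensor."""
    B, H, Wd, nine_c = cols.shape
    return (cols.reshape(B * H * Wd, nine_c) @ Wm).reshape(B, H, Wd, -1)


def conv_weight_grad(cols: np.ndarray, dy: np.ndarray, c_in: int) -> np.ndarray:
    """Kernel gradient from cached patches and the output gradient."""
    B, H, Wd, nine_c = cols.shape
    dy_m = dy.reshape(B * H * Wd, -1)
    dWm = cols.reshape(B * H * Wd, nine_c).T @ dy_m
    return matrix_kernel(dWm, c_in)


def flip_kernel_matrix(W: np.ndarray) -> np.ndarray:
    """GEMM matrix of the kernel that backpropagates through `conv2d_same`."""
    W_flip = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    return kernel_matrix(np.ascontiguousarray(W_flip))


def conv2d_same_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of `conv2d_same`."""
    cols = im2col_same(x)
    dW = conv_weight_grad(cols, dy, x.shape[-1])
    db = dy.sum(axis=(0, 1, 2))
    dx = conv_from_cols(im2col_same(dy), flip_kernel_matrix(W))
    return dx, dW, db


def _pool_cols(x: np.ndarray) -> tuple[np.ndarray, int, int]:
    B, H, Wd, C = x.shape
    Ho, Wo = (H - 3) // 2 + 1, (Wd - 3) // 2 + 1
    cols = np.empty((B, Ho, Wo, 9 * C), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            j = 3 * u + v
            cols[..., j * C : (j + 1) * C] = x[
                :, u : u + 2 * Ho : 2, v : v + 2 * Wo : 2, :
            ]
    return cols, Ho, Wo


def conv2d_pool(x: np.ndarray, W: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """3x3 convolution with stride 2, no padding (learned 2x down-sampling)."""
    cols, Ho, Wo = _pool_cols(x)
    y = conv_from_cols(cols, kernel_matrix(W))
    if b is not None:
        y += b
    return y


def conv2d_pool_backward(
    x: np.ndarray, W: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of `conv2d_pool`."""
    C = x.shape[-1]
    cols, Ho, Wo = _pool_cols(x)
    dW = conv_weight_grad(cols, dy, C)
    db = dy.sum(axis=(0, 1, 2))
    B = x.shape[0]
    dcols = (dy.reshape(B * Ho * Wo, -1) @ kernel_matrix(W).T).reshape(
        B, Ho, Wo, 9 * C
    )
    dx = np.zeros_like(x)
    for u in range(3):
        for v in range(3):
            j = 3 * u + v
            dx[:, u : u + 2 * Ho : 2, v : v + 2 * Wo : 2, :] += dcols[
                ..., j * C : (j + 1) * C
            ]
    return dx, dW, db


def pool2x2(x: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray | None]:
    """2x2 stride-2 max or average pooling; returns (y, argmax-cache)."""
    B, H, W, C = x.shape
    Ho, Wo = H // 2, W // 2
    v = x[:, : 2 * Ho, : 2 * Wo, :].reshape(B, Ho, 2, Wo, 2, C)
    if kind == "avg":
        return v.mean(axis=(2, 4)), None
    flat = v.transpose(0, 1, 3, 5, 2, 4).reshape(B, Ho, Wo, C, 4)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return y, arg


def pool2x2_backward(
    x_shape: tuple, dy: np.ndarray, kind: str, arg: np.ndarray | None
) -> np.ndarray:
    B, H, W, C = x_shape
    Ho, Wo = H // 2, W // 2
    if kind == "avg":
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, : 2 * Ho, : 2 * Wo, :] = (
            np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
        )
        return dx
    dflat = np.zeros((B, Ho, Wo, C, 4), dtype=dy.dtype)
    np.put_along_axis(dflat, arg[..., None], dy[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, : 2 * Ho, : 2 * Wo, :] = (
        dflat.reshape(B, Ho, Wo, C, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(B, 2 * Ho, 2 * Wo, C)
    )
    return dx


class Adam:
    """ADAM optimizer over a dict of parameter arrays (in-place updates)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self._buf = {k: np.empty_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        scale = lr / bias1
        for k, g in grads.items():
            m, v, buf = self.m[k], self.v[k], self._buf[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            np.multiply(g, g, out=buf)
            buf *= 1 - b2
            v += buf
            np.divide(v, bias2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= scale
            params[k] -= buf
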