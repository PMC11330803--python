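"""Quantification suite: MAE, NCC, SSIM, PSNR, RMSE, MAPE.

Applied both in coefficient space (MAE/MAPE on predicted vs. true PCA
labels) and in image space (NCC/SSIM/PSNR/RMSE on reconstructed slices or
volumes).  NCC is the standard zero-normalized cross correlation; SSIM is
the single-scale structural similarity with a Gaussian window.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter


def _as_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute error (1/m) sum |y_hat - y|."""
    y, y_hat = _as_pair(y, y_hat)
    return float(np.mean(np.abs(y_hat - y)))


def ncc(S: np.ndarray, T: np.ndarray) -> float:
    """Zero-normalized cross correlation in [-1, 1]; undefined for constant images."""
    S, T = _as_pair(S, T)
    s = S - S.mean()
    t = T - T.mean()
    denom = np.sqrt(np.sum(s * s) * np.sum(t * t))
    if denom == 0:
        raise ValueError("NCC is undefined for constant images")
    return float(np.sum(s * t) / denom)


def ssim(
    S: np.ndarray,
    T: np.ndarray,
    data_range: float,
    sigma: float = 1.5,
    truncate: float = 3.5,
    k1: float = 0.01,
    k2: float = 0.03,
    multiscale: bool = False,
) -> float:
    """Mean local structural similarity with a Gaussian window.

    C1 = (k1 L)^2 and C2 = (k2 L)^2 with L = ``data_range``.  Local means,
    variances and covariance are Gaussian-weighted (sigma 1.5, 11x11
    support); the map is averaged after cropping the window's half-width
    at the borders.  ``multiscale=True`` averages SSIM over a dyadic
    pyramid (2 extra scales) instead of the single-scale value.
    """
    S, T = _as_pair(S, T)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if multiscale:
        vals = []
        s, t = S, T
        for _ in range(3):
            vals.append(ssim(s, t, data_range, sigma, truncate, k1, k2))
            if min(s.shape) < 24:
                break
            s = 0.25 * (s[0::2, 0::2] + s[1::2, 0::2] + s[0::2, 1::2] + s[1::2, 1::2]) \
                if s.ndim == 2 else s
            t = 0.25 * (t[0::2, 0::2] + t[1::2, 0::2] + t[0::2, 1::2] + t[1::2, 1::2]) \
                if t.ndim == 2 else t
        return float(np.mean(vals))

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def filt(img):
        return gaussian_filter(img, sigma=sigma, truncate=truncate, mode="nearest")

    ux = filt(S)
    uy = filt(T)
    uxx = filt(S * S)
    uyy = filt(T * T)
    uxy = filt(S * T)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    num = (2 * ux * uy + c1) * (2 * vxy + c2)
    den = (ux**2 + uy**2 + c1) * (vx + vy + c2)
    ssim_map = num / den

    pad = int(truncate * sigma + 0.5)
    if all(n > 2 * pad for n in ssim_map.shape):
        sl = tuple(slice(pad, n - pad) for n in ssim_map.shape)
        ssim_map = ssim_map[sl]
    return float(ssim_map.mean())


def psnr(S: np.ndarray, T: np.ndarray, max_value: float | None = None) -> float:
    """10 log10(MAX^2 / MSE) in dB; +inf for identical images.

    MAX defaults to the reference image's maximum value.
    """
    S, T = _as_pair(S, T)
    mse = float(np.mean((S - T) ** 2))
    if max_value is None:
        max_value = float(np.max(T))
    if mse == 0.0:
        return float("inf")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    return float(10.0 * np.log10(max_value**2 / mse))


def rmse(S: np.ndarray, T: np.ndarray) -> float:
    """Root mean squared difference."""
    S, T = _as_pair(S, T)
    return float(np.sqrt(np.mean((S - T) ** 2)))


def mape(
    S: np.ndarray,
    T: np.ndarray,
    eps_fraction: float = 1e-6,
    with_count: bool = False,
):
    """Mean |S - T| / |T| over entries where |T| is bounded away from zero.

    Reference entries with |T| <= eps_fraction * max|T| are masked out
    (PCA coefficients cross zero, where the ratio is meaningless).  With
    ``with_count=True`` also returns the number of entries used.
    """
    S, T = _as_pair(S, T)
    eps = eps_fraction * np.max(np.abs(T)) if T.size else 0.0
    mask = np.abs(T) > eps
    if not np.any(mask):
        raise ValueError("all reference entries masked (|T| ~ 0)")
    value = float(np.mean(np.abs(S[mask] - T[mask]) / np.abs(T[mask])))
    if with_count:
        return value, int(mask.sum())
    return value


def metric_report(
    recon: np.ndarray,
    truth: np.ndarray,
    data_range: float | None = None,
) -> dict:
    """All six metrics for one reconstructed-vs-truth image pair."""
    recon, truth = _as_pair(recon, truth)
    if data_range is None:
        data_range = float(truth.max() - truth.min())
    p = psnr(recon, truth)
    return {
        "mae": mae(truth.ravel(), recon.ravel()),
        "ncc": ncc(recon, truth),
        "ssim": ssim(recon, truth, data_range=data_range),
        "psnr": None if np.isinf(p) else p,
        "rmse": rmse(recon, truth),
        "mape": mape(recon.ravel(), truth.ravel()),
    }
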