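"""PCA respiratory motion model over deformation vector fields.

A stack of per-phase DVFs (each flattened to a 3N vector) is mean-centered
and decomposed with an SVD; every phase field is then represented as

    DVF(i) = mean + sum_j q_j(i) * p_j,        j = 1..k

with global orthonormal eigen-fields ``p_j`` and per-phase coefficients
``q_j`` (the "PCA labels" the network regresses).  The SVD route is used
instead of the 3N x 3N covariance because 3N is large and the results are
identical.  The full spectrum is retained even when k < rank so the
cumulative-information curve can be reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .types import CoefficientVector, DVFVolume, Volume3D


@dataclass
class PCAMotionModel:
    mean_dvf: np.ndarray            # (3N,)
    components: np.ndarray          # (rank, 3N), orthonormal rows, eigenvalue order
    explained_ratios: np.ndarray    # (rank,), sums to 1 over the retained spectrum
    k: int                          # truncation order used for synthesis/projection
    grid_dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def rank(self) -> int:
        return self.components.shape[0]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            mean_dvf=self.mean_dvf,
            components=self.components,
            explained_ratios=self.explained_ratios,
            k=self.k,
            grid_dims=np.asarray(self.grid_dims),
            spacing=np.asarray(self.spacing),
            origin=np.asarray(self.origin),
        )

    @classmethod
    def load(cls, path) -> "PCAMotionModel":
        with np.load(path) as z:
            return cls(
                mean_dvf=z["mean_dvf"],
                components=z["components"],
                explained_ratios=z["explained_ratios"],
                k=int(z["k"]),
                grid_dims=tuple(int(v) for v in z["grid_dims"]),
                spacing=tuple(float(v) for v in z["spacing"]),
                origin=tuple(float(v) for v in z["origin"]),
            )


@dataclass(frozen=True)
class SamplingSpec:
    """Monte-Carlo coefficient sampling with amplitude-range expansion.

    ``expansion`` widens the per-component coefficient range seen in the
    source phases by the given fraction up and down (default 15%), so the
    simulated motion covers slightly more than the binned phase motion.
    """

    n_samples: int = 900
    expansion: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.expansion < 0:
            raise ValueError("expansion must be >= 0")


def fit_pca(dvfs: list[DVFVolume], k: int = 3) -> PCAMotionModel:
    """Mean-centered PCA of a DVF stack; k is the synthesis truncation order."""
    if len(dvfs) < 2:
        raise ValueError("need at least 2 DVFs")
    if k < 1:
        raise ValueError("k must be >= 1")
    ref = dvfs[0]
    for d in dvfs[1:]:
        if not ref.same_grid(d):
            raise ValueError("all DVFs must share one grid")
    X = np.stack([d.flatten() for d in dvfs]).astype(np.float64)  # (n, 3N)
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: Xc = U S Vt, rows of Vt are the eigen-fields
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2
    tol = variances[0] * 1e-12 if variances.size and variances[0] > 0 else 0.0
    nz = int(np.sum(variances > tol))
    nz = max(nz, 1)
    components = Vt[:nz]
    ratios = variances[:nz] / variances[:nz].sum() if variances[:nz].sum() > 0 else np.ones(nz) / nz
    if k > nz:
        warnings.warn(f"k={k} exceeds spectrum rank {nz}; clamping")
        k = nz
    return PCAMotionModel(
        mean_dvf=mean,
        components=components,
        explained_ratios=ratios,
        k=k,
        grid_dims=ref.grid_dims,
        spacing=ref.spacing,
        origin=ref.origin,
    )


def information_curve(model: PCAMotionModel) -> list[tuple[int, float, float]]:
    """(n_components, cumulative %, increment %) over the retained spectrum.

    Cumulative information is the running sum of explained-variance ratios,
    expressed in percent; it reaches 100 at full rank.
    """
    cum = np.cumsum(model.explained_ratios) * 100.0
    out = []
    prev = 0.0
    for j, c in enumerate(cum, start=1):
        out.append((j, float(c), float(c - prev)))
        prev = float(c)
    return out


def synthesize_dvf(model: PCAMotionModel, q: CoefficientVector | np.ndarray) -> DVFVolume:
    """mean + sum_j q_j p_j, reshaped to the model grid (first k components)."""
    qv = q.q if isinstance(q, CoefficientVector) else np.asarray(q, dtype=float)
    if qv.shape != (model.k,):
        raise ValueError(f"expected {model.k} coefficients, got {qv.shape}")
    flat = model.mean_dvf + qv @ model.components[: model.k]
    d = flat.reshape(model.grid_dims + (3,))
    return DVFVolume(displacement=d, spacing=model.spacing, origin=model.origin)


def project_dvf(model: PCAMotionModel, dvf: DVFVolume) -> CoefficientVector:
    """Least-squares optimal coefficients q_j = p_j . (dvf - mean)."""
    if dvf.grid_dims != model.grid_dims:
        raise ValueError("DVF grid does not match the model grid")
    centered = dvf.flatten().astype(np.float64) - model.mean_dvf
    q = model.components[: model.k] @ centered
    return CoefficientVector(q=q, phase_tag=dvf.phase_tag)


def sample_coefficients(
    model: PCAMotionModel,
    phases: list[CoefficientVector] | np.ndarray,
    spec: SamplingSpec,
) -> list[CoefficientVector]:
    """Uniform independent sampling per component over expanded phase ranges.

    For component j with phase-coefficient range [min_j, max_j] and span
    R_j, samples are uniform on [min_j - e R_j, max_j + e R_j] with
    e = ``spec.expansion``.
    """
    P = (
        np.stack([p.q for p in phases])
        if not isinstance(phases, np.ndarray)
        else np.asarray(phases, dtype=float)
    )
    if P.ndim != 2 or P.shape[1] != model.k:
        raise ValueError(f"phase coefficients must have shape (n_phases, {model.k})")
    lo = P.min(axis=0)
    hi = P.max(axis=0)
    R = hi - lo
    if np.all(R == 0):
        raise ValueError("degenerate motion: all phase coefficients identical")
    lo_e = lo - spec.expansion * R
    hi_e = hi + spec.expansion * R
    rng = np.random.default_rng(spec.seed)
    samples = rng.uniform(lo_e, hi_e, size=(spec.n_samples, model.k))
    return [CoefficientVector(q=s) for s in samples]


def warp_volume(vol: Volume3D, dvf: DVFVolume) -> Volume3D:
    """Trilinear pull-back resampling: output(x) = input(x + d(x)).

    Samples falling outside the grid are filled with 0 (air).
    """
    if not vol.same_grid(dvf):
        raise ValueError("volume and DVF grids do not match")
    idx = np.indices(vol.grid_dims, dtype=float)          # (3, nx, ny, nz)
    disp_vox = np.moveaxis(dvf.displacement, -1, 0) / np.asarray(vol.spacing)[
        :, None, None, None
    ]
    coords = idx + disp_vox
    values = map_coordinates(
        np.asarray(vol.values, dtype=float), coords, order=1, mode="constant", cval=0.0
    )
    return Volume3D(values=values, spacing=vol.spacing, origin=vol.origin)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross correlation (re-exported from metrics for convenience)."""
    from .metrics import ncc as _ncc

    return _ncc(a, b)
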