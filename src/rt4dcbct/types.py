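"""Core grid-attached containers shared by every pipeline stage.

Conventions used throughout the package:

* Arrays are indexed ``[ix, iy, iz]`` with x = left-right (LR), y =
  anterior-posterior (AP) and z = inferior-superior (SI).  The SI axis is
  the gantry rotation axis.
* Physical coordinates are in millimetres.  Voxel ``(i, j, k)`` has its
  centre at ``origin + (i, j, k) * spacing``.
* Displacement fields use the pull-back convention: the warped image at
  position ``x`` samples the source image at ``x + d(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume3D:
    """Scalar attenuation volume (mm^-1) on a regular grid."""

    values: np.ndarray          # (nx, ny, nz)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume3D | DVFVolume") -> bool:
        return (
            self.grid_dims == other.grid_dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of the voxel-centre lattice, one 1-D array per axis."""
        return tuple(
            self.origin[a] + np.arange(self.grid_dims[a]) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class DVFVolume:
    """Per-voxel 3-component displacement field (mm), pull-back convention.

    ``displacement`` has shape ``(nx, ny, nz, 3)``; flattened it holds
    3 * N_voxel values, the vector the PCA motion model operates on.
    """

    displacement: np.ndarray    # (nx, ny, nz, 3), mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    phase_tag: int | None = None

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError(
                f"expected (nx, ny, nz, 3) array, got shape {self.displacement.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("DVF contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]

    def flatten(self) -> np.ndarray:
        """The 3*N vector fed to the PCA model (C order)."""
        return self.displacement.reshape(-1)

    def same_grid(self, other: "Volume3D | DVFVolume") -> bool:
        return (
            self.grid_dims == other.grid_dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class CoefficientVector:
    """Truncated PCA mode amplitudes (mm-weighted) describing one breathing state."""

    q: np.ndarray
    phase_tag: int | None = None

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        if self.q.ndim != 1:
            raise ValueError("coefficient vector must be 1-D")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("coefficients must be finite")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class DRRImage:
    """Line-integral projection image (dimensionless) at one gantry angle."""

    line_integrals: np.ndarray  # (nu, nv)
    geometry: "object | None" = None
    noise_applied: bool = False

    def __post_init__(self) -> None:
        self.line_integrals = np.asarray(self.line_integrals, dtype=float)
        if self.line_integrals.ndim != 2:
            raise ValueError("DRR must be a 2-D image")
        if not np.all(np.isfinite(self.line_integrals)):
            raise ValueError("DRR contains non-finite values")


def centered_origin(grid_dims, spacing) -> tuple[float, float, float]:
    """Origin that centres the voxel lattice on the world origin (isocentre)."""
    return tuple(
        -0.5 * (n - 1) * s for n, s in zip(grid_dims, spacing)
    )  # type: ignore[return-value]
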