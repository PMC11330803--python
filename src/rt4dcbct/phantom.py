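"""Analytic 4-D thorax phantom with ground-truth deformation fields.

The phantom provides what a 4D-CT plus deformable registration would in a
clinical pipeline: a reference attenuation volume, per-phase deformed
volumes, and the exact deformation vector field (DVF) that links each phase
to the 0% reference.  Anatomy is a handful of soft-edged ellipsoids (body,
two lungs, diaphragm dome, tumor); motion is a smooth, superior-inferior
dominant displacement field whose strength follows a periodic breathing
trace.

Because the deformed volume is produced by *analytically* evaluating the
reference attenuation at the displaced coordinates ``x + d(x)`` (pull-back
convention), phase volumes and DVFs are exactly consistent: numerically
warping the reference with the stored DVF reproduces the phase volume up to
interpolation error only.

Besides the main amplitude-driven motion mode the per-phase fields carry a
second (amplitude-squared) chest-wall term and a set of small harmonic
perturbation fields.  These emulate the inhale/exhale asymmetry and
registration irregularities of real 4D-CT-derived DVFs and guarantee that
the non-reference phase fields are linearly independent, so a PCA of the
stack has a full, gradually decaying spectrum instead of a single mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import DVFVolume, Volume3D, centered_origin

MAX_AMPLITUDE = 1.15  # amplitudes are valid in [0, MAX_AMPLITUDE]

# number of independent motion basis fields (1 main + 1 chest wall + 7 harmonic)
N_MOTION_FIELDS = 9


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]      # mm, world coordinates
    semi_axes: tuple[float, float, float]   # mm
    mu: float                               # attenuation, mm^-1

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.mu < 0:
            raise ValueError("attenuation must be non-negative")

    def quadratic(self, pts: np.ndarray) -> np.ndarray:
        """sum(((x - c) / a)^2); < 1 inside the ellipsoid."""
        c = np.asarray(self.center)
        a = np.asarray(self.semi_axes)
        return np.sum(((pts - c) / a) ** 2, axis=-1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, attenuation and motion parameters of the synthetic thorax.

    ``max_displacement`` is the signed displacement (mm) of the tumor (and
    diaphragm region) at breathing amplitude 1; it is SI-dominant, with the
    AP and LR components at roughly 30% and 10% of the SI excursion.
    """

    grid_dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body: Ellipsoid = Ellipsoid((0.0, 0.0, 0.0), (115.0, 88.0, 118.0), 0.020)
    lung_left: Ellipsoid = Ellipsoid((-52.0, 0.0, 15.0), (40.0, 52.0, 82.0), 0.004)
    lung_right: Ellipsoid = Ellipsoid((52.0, 0.0, 15.0), (40.0, 52.0, 82.0), 0.004)
    tumor: Ellipsoid = Ellipsoid((52.0, 8.0, -25.0), (10.0, 10.0, 10.0), 0.030)
    diaphragm: Ellipsoid = Ellipsoid((0.0, 0.0, -110.0), (100.0, 70.0, 55.0), 0.025)
    max_displacement: tuple[float, float, float] = (1.2, 3.6, -12.0)
    # amplitudes (mm) of the seven harmonic perturbation fields used by
    # generate_4dct; small relative to the main SI excursion
    harmonic_mm: tuple[float, ...] = (0.6, 0.45, 0.3, 0.2, 0.5, 0.35, 0.15)
    edge_mm: float = 6.0        # soft-edge width of the ellipsoid interfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_dims) < 16:
            raise ValueError("grid_dims must be >= 16 per axis")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if len(self.harmonic_mm) != N_MOTION_FIELDS - 2:
            raise ValueError(f"expected {N_MOTION_FIELDS - 2} harmonic amplitudes")
        self._check_tumor_in_lung()

    def _check_tumor_in_lung(self) -> None:
        # Tumor and lung are advected by the same smooth displacement map,
        # so containment at the reference configuration (with margin) holds
        # at every amplitude.  Sample the tumor surface and require it to
        # sit strictly inside one lung.
        n = 256
        idx = np.arange(n)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        zc = 1.0 - 2.0 * (idx + 0.5) / n
        r = np.sqrt(np.clip(1.0 - zc**2, 0.0, None))
        th = golden * idx
        unit = np.stack([r * np.cos(th), r * np.sin(th), zc], axis=-1)
        surface = np.asarray(self.tumor.center) + unit * np.asarray(self.tumor.semi_axes)
        inside = np.minimum(
            self.lung_left.quadratic(surface), self.lung_right.quadratic(surface)
        )
        if np.any(np.sqrt(inside) > 0.97):
            raise ValueError("tumor ellipsoid must sit strictly inside a lung")

    @property
    def origin(self) -> tuple[float, float, float]:
        return centered_origin(self.grid_dims, self.spacing)


def default_spec(n: int = 64, fov_mm: float = 256.0, **overrides) -> PhantomSpec:
    """Isotropic n^3 spec covering a fixed 256 mm field of view."""
    return PhantomSpec(
        grid_dims=(n, n, n), spacing=(fov_mm / n,) * 3, **overrides
    )


@dataclass(frozen=True)
class BreathingTrace:
    """Periodic per-phase breathing amplitudes, a(0) = 0 at the reference phase."""

    amplitudes: tuple[float, ...]
    n_phases: int = 10
    model: str = "cos2"

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        if a.size != self.n_phases:
            raise ValueError("amplitudes length must equal n_phases")
        if abs(a[0]) > 1e-12:
            raise ValueError("reference phase must have zero amplitude")
        if a.min() < 0 or a.max() > MAX_AMPLITUDE:
            raise ValueError(f"amplitudes must lie in [0, {MAX_AMPLITUDE}]")

    @classmethod
    def cos2(cls, n_phases: int = 10, a_max: float = 1.0) -> "BreathingTrace":
        """a_i = a_max * (1 - cos(2 pi i / n)) / 2 : zero at phase 0, peak mid-cycle."""
        i = np.arange(n_phases)
        a = a_max * (1.0 - np.cos(2.0 * np.pi * i / n_phases)) / 2.0
        a[0] = 0.0
        return cls(amplitudes=tuple(a), n_phases=n_phases, model="cos2")


# ----------------------------------------------------------------------------
# attenuation model
# ----------------------------------------------------------------------------

def _soft_inside(ell: Ellipsoid, pts: np.ndarray, edge_mm: float) -> np.ndarray:
    """Smooth 0..1 indicator of the ellipsoid with an edge ~edge_mm wide."""
    q = np.sqrt(np.maximum(ell.quadratic(pts), 0.0))
    # (1 - q) * a_min approximates the signed distance to the surface
    t = (1.0 - q) * min(ell.semi_axes) / max(edge_mm, 1e-6)
    return 0.5 * (1.0 + np.tanh(2.0 * t))


def attenuation_at(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Reference-phase attenuation mu(x) (mm^-1) at arbitrary world points."""
    e = spec.edge_mm
    w_body = _soft_inside(spec.body, pts, e)
    w_lung = np.clip(
        _soft_inside(spec.lung_left, pts, e) + _soft_inside(spec.lung_right, pts, e),
        0.0, 1.0,
    )
    w_dia = _soft_inside(spec.diaphragm, pts, e)
    w_tum = _soft_inside(spec.tumor, pts, e)

    mu = spec.body.mu * w_body
    mu += (spec.lung_left.mu - spec.body.mu) * w_lung * w_body
    mu += (spec.diaphragm.mu - spec.lung_left.mu) * w_dia * w_lung
    mu += (spec.tumor.mu - spec.lung_left.mu) * w_tum * w_body
    return np.maximum(mu, 0.0)


# ----------------------------------------------------------------------------
# motion model: 9 smooth basis fields with per-phase coefficients
# ----------------------------------------------------------------------------

def _si_weight(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    """SI taper: full motion below the carina level, zero at the lung apex."""
    z0, z1 = -10.0, 90.0
    t = np.clip((z - z0) / (z1 - z0), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)   # 1 - smoothstep


def _chest_weight(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Anterior chest-wall region (y towards the sternum), away from the tumor."""
    y, z = pts[..., 1], pts[..., 2]
    ty = np.clip((y - 20.0) / 50.0, 0.0, 1.0)
    tz = np.clip(1.0 - np.abs(z - 10.0) / 110.0, 0.0, 1.0)
    return ty * ty * (3.0 - 2.0 * ty) * tz


def _harmonic_fields(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Seven small, smooth, linearly independent vector fields, shape (7, ..., 3)."""
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    hx = 0.5 * float(spec.grid_dims[0]) * spec.spacing[0]
    hy = 0.5 * float(spec.grid_dims[1]) * spec.spacing[1]
    hz = 0.5 * float(spec.grid_dims[2]) * spec.spacing[2]
    sx, sy, sz = x / hx, y / hy, z / hz      # roughly [-1, 1]
    p = np.pi
    patterns = [
        (np.sin(0.5 * p * sz) * np.cos(0.25 * p * sx), 2),
        (np.sin(0.5 * p * sy) * np.cos(0.5 * p * sz), 1),
        (np.sin(0.5 * p * sx) * np.cos(0.5 * p * sy), 0),
        (np.cos(0.5 * p * sx) * np.sin(p * sz) * 0.8, 2),
        (np.cos(0.5 * p * sz) * np.cos(0.5 * p * sy), 1),
        (np.sin(p * sy) * np.cos(0.25 * p * sz), 2),
        (np.cos(0.5 * p * sy) * np.sin(0.5 * p * sz), 0),
    ]
    out = np.zeros((len(patterns),) + pts.shape)
    for h, (pat, axis) in enumerate(patterns):
        out[h, ..., axis] = pat
    return out


def motion_coefficients(
    spec: PhantomSpec,
    amplitude: float,
    phase_angle: float | None = None,
) -> np.ndarray:
    """Coefficients of the 9 motion basis fields for one breathing state.

    The first two entries are amplitude-driven (main SI mode and the
    quadratic chest-wall mode).  The harmonic entries depend on the phase
    *angle* within the cycle and vanish when no angle is given (the scalar
    amplitude API) and at the reference phase (angle 0).
    """
    c = np.zeros(N_MOTION_FIELDS)
    c[0] = amplitude
    c[1] = amplitude * amplitude
    if phase_angle is not None:
        th = float(phase_angle)
        eps = np.asarray(spec.harmonic_mm, dtype=float)
        trig = np.array(
            [
                np.sin(th), np.sin(2 * th), np.sin(3 * th), np.sin(4 * th),
                np.cos(3 * th) - 1.0, np.cos(4 * th) - 1.0, np.cos(5 * th) - 1.0,
            ]
        )
        c[2:] = eps * trig
    return c


def displacement_at(
    spec: PhantomSpec, coeffs: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Pull-back displacement d(x) (mm) for one set of motion coefficients.

    The sign convention makes anatomy move by approximately ``+c0 * w * m``:
    the deformed volume at x samples the reference at ``x + d(x)``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    m = np.asarray(spec.max_displacement, dtype=float)
    w = _si_weight(spec, pts[..., 2])
    d = -coeffs[0] * w[..., None] * m
    ap_amp = abs(spec.max_displacement[2]) / 3.0
    d[..., 1] += -coeffs[1] * _chest_weight(spec, pts) * ap_amp
    if np.any(coeffs[2:] != 0.0):
        fields = _harmonic_fields(spec, pts)
        for h in range(fields.shape[0]):
            if coeffs[2 + h] != 0.0:
                d += coeffs[2 + h] * fields[h]
    return d


def _voxel_points(spec: PhantomSpec) -> np.ndarray:
    ax = [
        spec.origin[a] + np.arange(spec.grid_dims[a]) * spec.spacing[a]
        for a in range(3)
    ]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


def _check_amplitude(amplitude: float) -> float:
    amplitude = float(amplitude)
    if not (0.0 <= amplitude <= MAX_AMPLITUDE):
        raise ValueError(
            f"amplitude must lie in [0, {MAX_AMPLITUDE}], got {amplitude}"
        )
    return amplitude


def _phantom_from_coeffs(spec: PhantomSpec, coeffs: np.ndarray) -> Volume3D:
    pts = _voxel_points(spec)
    d = displacement_at(spec, coeffs, pts)
    values = attenuation_at(spec, pts + d)
    return Volume3D(values=values, spacing=spec.spacing, origin=spec.origin)


def make_phantom(spec: PhantomSpec, amplitude: float) -> Volume3D:
    """Thorax volume at one breathing amplitude (0 = reference full exhale)."""
    amplitude = _check_amplitude(amplitude)
    return _phantom_from_coeffs(spec, motion_coefficients(spec, amplitude))


def ground_truth_dvf(spec: PhantomSpec, amplitude: float) -> DVFVolume:
    """Exact pull-back DVF linking the reference volume to one amplitude."""
    amplitude = _check_amplitude(amplitude)
    pts = _voxel_points(spec)
    d = displacement_at(spec, motion_coefficients(spec, amplitude), pts)
    return DVFVolume(displacement=d, spacing=spec.spacing, origin=spec.origin)


def generate_4dct(
    spec: PhantomSpec, trace: BreathingTrace
) -> tuple[list[Volume3D], list[DVFVolume]]:
    """One volume and one ground-truth DVF per breathing phase.

    Phase 0 is the reference: its DVF is identically zero and its volume is
    the reference volume.  Non-reference phases combine the amplitude-driven
    modes with the small phase-harmonic perturbations, which makes the
    non-reference DVFs linearly independent.
    """
    if trace.n_phases < 3:
        raise ValueError("need at least 3 phases")
    amps = np.asarray(trace.amplitudes, dtype=float)
    if np.all(amps == 0.0):
        warnings.warn("degenerate breathing trace: all amplitudes are zero")
    pts = _voxel_points(spec)
    volumes: list[Volume3D] = []
    dvfs: list[DVFVolume] = []
    for i in range(trace.n_phases):
        angle = 2.0 * np.pi * i / trace.n_phases
        c = motion_coefficients(spec, amps[i], phase_angle=angle)
        if i == 0:
            d = np.zeros(pts.shape)
        else:
            d = displacement_at(spec, c, pts)
        values = attenuation_at(spec, pts + d)
        volumes.append(Volume3D(values=values, spacing=spec.spacing, origin=spec.origin))
        dvfs.append(
            DVFVolume(displacement=d, spacing=spec.spacing, origin=spec.origin, phase_tag=i)
        )
    return volumes, dvfs
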