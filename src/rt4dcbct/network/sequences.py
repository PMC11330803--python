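"""Temporally ordered DRR training sequences from the PCA motion model.

The training set is built the way the projections would arrive in use:
frames are ordered along simulated breathing traces in coefficient space.
A continuous phase variable advances through repeated cycles; each cycle's
coefficient trajectory is the periodic interpolation of the per-phase PCA
coefficients, scaled by a per-cycle amplitude factor drawn from the +/-15%
expanded range, with small per-frame, per-component jitter.  Every frame is
rendered once (synthesize DVF -> warp reference -> project -> noise ->
per-image z-score); training samples are sliding windows of T consecutive
frames labelled by the coefficients of the final frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..motion import PCAMotionModel, synthesize_dvf, warp_volume
from ..projector import ConeBeamGeometry, NoiseModel, add_noise, forward_project
from ..types import Volume3D


@dataclass(frozen=True)
class SequenceSimConfig:
    """Study conditions for training-data simulation.

    Defaults follow the simulation design: ~900 frames of continuous
    breathing at one gantry angle, +/-15% amplitude expansion, quantum
    noise at I0 = 1e5 with electronic variance 10.
    """

    n_frames: int = 900
    frames_per_cycle: int = 24      # ~4 s breathing cycle at ~6 fps
    sequence_length: int = 4
    expansion: float = 0.15
    jitter: float = 0.03            # per-frame coefficient jitter, fraction of range
    noise: NoiseModel | None = NoiseModel()
    normalize: bool = True
    seed: int = 0


def periodic_trajectory(phase_coeffs: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Linear periodic interpolation of per-phase coefficients.

    ``phase_coeffs`` is (n_phases, k) with phases at fractions i/n of the
    cycle; ``phi`` holds cycle fractions (any real, wrapped mod 1).
    Returns (len(phi), k).
    """
    P = np.asarray(phase_coeffs, dtype=float)
    n = P.shape[0]
    grid = np.arange(n + 1) / n
    Pw = np.vstack([P, P[:1]])          # close the cycle
    phi = np.mod(np.asarray(phi, dtype=float), 1.0)
    return np.stack(
        [np.interp(phi, grid, Pw[:, j]) for j in range(P.shape[1])], axis=-1
    )


def simulate_frame(
    model: PCAMotionModel,
    q: np.ndarray,
    reference: Volume3D,
    geom: ConeBeamGeometry,
    noise: NoiseModel | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Render one projection frame for one coefficient vector."""
    dvf = synthesize_dvf(model, np.asarray(q, dtype=float))
    vol = warp_volume(reference, dvf)
    drr = forward_project(vol, geom)
    if noise is not None:
        drr = add_noise(drr, noise)
    img = drr.line_integrals.astype(np.float32)
    if normalize:
        std = img.std()
        img = (img - img.mean()) / (std if std > 0 else 1.0)
    return img


def _frame_coefficients(
    phase_coeffs: np.ndarray, cfg: SequenceSimConfig, rng: np.random.Generator
) -> np.ndarray:
    P = np.asarray(phase_coeffs, dtype=float)
    k = P.shape[1]
    R = P.max(axis=0) - P.min(axis=0)
    n_cycles = int(np.ceil(cfg.n_frames / cfg.frames_per_cycle))
    scales = rng.uniform(1.0 - cfg.expansion, 1.0 + cfg.expansion, size=n_cycles)
    t = np.arange(cfg.n_frames)
    phi = t / cfg.frames_per_cycle
    cycle = (t // cfg.frames_per_cycle).astype(int)
    q = periodic_trajectory(P, phi) * scales[cycle][:, None]
    q += rng.uniform(-cfg.jitter, cfg.jitter, size=(cfg.n_frames, k)) * R[None, :]
    return q


def build_training_sequences(
    model: PCAMotionModel,
    phase_coeffs: np.ndarray,
    reference: Volume3D,
    geom: ConeBeamGeometry,
    cfg: SequenceSimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate frames along breathing traces and window them into sequences.

    Returns ``(sequences, labels)`` with sequences of shape
    (n_frames - T + 1, T, n_u, n_v) and labels (n_frames - T + 1, k): each
    window of T consecutive frames is labelled by its final frame's
    coefficients (causal, real-time semantics).
    """
    T = cfg.sequence_length
    if cfg.n_frames < T:
        raise ValueError("need at least sequence_length frames")
    rng = np.random.default_rng(cfg.seed)
    q = _frame_coefficients(phase_coeffs, cfg, rng)
    noise_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_frames)
    frames = np.empty(
        (cfg.n_frames,) + tuple(geom.detector_size), dtype=np.float32
    )
    for t in range(cfg.n_frames):
        noise = (
            replace(cfg.noise, seed=int(noise_seeds[t])) if cfg.noise is not None else None
        )
        frames[t] = simulate_frame(
            model, q[t], reference, geom, noise=noise, normalize=cfg.normalize
        )
    windows = sliding_window_view(frames, T, axis=0)       # (N, nu, nv, T)
    sequences = np.ascontiguousarray(np.moveaxis(windows, -1, 1))
    labels = q[T - 1 :]
    return sequences, labels


def build_phase_stream(
    model: PCAMotionModel,
    phase_volumes: list[Volume3D],
    geom: ConeBeamGeometry,
    cfg: SequenceSimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Test-time projection stream covering one full respiratory cycle.

    Projects the given per-phase volumes in phase order, prepending the
    last T-1 phases (periodic wrap) so that a causal sliding window of
    length T produces exactly one prediction per phase, labelled 0..n-1.

    Returns ``(frames, phase_of_window_end)``.
    """
    T = cfg.sequence_length
    n = len(phase_volumes)
    if n < 1:
        raise ValueError("need at least one phase volume")
    order = [(i - (T - 1)) % n for i in range(n + T - 1)]
    rng = np.random.default_rng(cfg.seed + 7919)
    frames = np.empty((len(order),) + tuple(geom.detector_size), dtype=np.float32)
    for j, i in enumerate(order):
        drr = forward_project(phase_volumes[i], geom)
        if cfg.noise is not None:
            noise = replace(cfg.noise, seed=int(rng.integers(0, 2**31 - 1)))
            drr = add_noise(drr, noise)
        img = drr.line_integrals.astype(np.float32)
        if cfg.normalize:
            std = img.std()
            img = (img - img.mean()) / (std if std > 0 else 1.0)
        frames[j] = img
    phases = np.asarray(order[T - 1 :], dtype=int)
    return frames, phases
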