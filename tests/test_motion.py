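"""PCA motion model: spectra, round trips, sampling law, warping."""

import numpy as np
import pytest

from rt4dcbct.motion import (
    PCAMotionModel,
    SamplingSpec,
    fit_pca,
    information_curve,
    project_dvf,
    sample_coefficients,
    synthesize_dvf,
    warp_volume,
)
from rt4dcbct.types import DVFVolume, Volume3D, centered_origin

GRID = (8, 8, 8)
SPACING = (4.0, 4.0, 4.0)
ORIGIN = centered_origin(GRID, SPACING)


def dvf_from_flat(flat, tag=None):
    return DVFVolume(
        displacement=np.asarray(flat, dtype=float).reshape(GRID + (3,)),
        spacing=SPACING,
        origin=ORIGIN,
        phase_tag=tag,
    )


def random_stack(rng, n, rank=None):
    """n DVFs spanning an affine subspace of the given rank."""
    dim = 3 * int(np.prod(GRID))
    rank = rank if rank is not None else n - 1
    basis = rng.normal(size=(rank, dim))
    coeffs = rng.normal(size=(n, rank))
    offset = rng.normal(size=dim)
    return [dvf_from_flat(offset + c @ basis, tag=i) for i, c in enumerate(coeffs)]


class TestFitPCA:
    def test_exact_low_rank_reconstruction(self, rng):
        dvfs = random_stack(rng, 9, rank=2)
        model = fit_pca(dvfs, k=2)
        for d in dvfs:
            q = project_dvf(model, d)
            rec = synthesize_dvf(model, q)
            err = np.linalg.norm(rec.flatten() - d.flatten())
            assert err <= 1e-8 * np.linalg.norm(d.flatten())

    def test_full_rank_round_trip(self, rng):
        dvfs = random_stack(rng, 6)
        model = fit_pca(dvfs, k=model_rank(dvfs))
        for d in dvfs:
            rec = synthesize_dvf(model, project_dvf(model, d))
            np.testing.assert_allclose(rec.flatten(), d.flatten(), atol=1e-8)

    def test_component_orthonormality(self, rng):
        model = fit_pca(random_stack(rng, 8), k=3)
        G = model.components @ model.components.T
        np.testing.assert_allclose(G, np.eye(model.rank), atol=1e-8)

    def test_k_clamped_with_warning(self, rng):
        dvfs = random_stack(rng, 4, rank=2)
        with pytest.warns(UserWarning, match="clamping"):
            model = fit_pca(dvfs, k=10)
        assert model.k == model.rank

    def test_grid_mismatch_rejected(self, rng):
        a = random_stack(rng, 3)
        bad = DVFVolume(
            displacement=np.zeros((4, 4, 4, 3)), spacing=SPACING, origin=ORIGIN
        )
        with pytest.raises(ValueError):
            fit_pca([a[0], bad])

    def test_truncation_error_monotone_in_k(self, rng):
        dvfs = random_stack(rng, 8)
        target = dvfs[3]
        errs = []
        for k in range(1, 8):
            model = fit_pca(dvfs, k=k)
            rec = synthesize_dvf(model, project_dvf(model, target))
            errs.append(np.linalg.norm(rec.flatten() - target.flatten()))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))


def model_rank(dvfs):
    X = np.stack([d.flatten() for d in dvfs])
    return np.linalg.matrix_rank(X - X.mean(0))


class TestInformationCurve:
    def test_matches_dense_eigendecomposition(self, rng):
        """Cumulative information equals the eigenvalue ratios of the dense
        covariance, computed by an independent route (eigh, not SVD)."""
        dvfs = random_stack(rng, 10)
        model = fit_pca(dvfs, k=3)
        X = np.stack([d.flatten() for d in dvfs])
        Xc = X - X.mean(0)
        # small-side covariance has the same nonzero spectrum
        lam = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]
        lam = lam[: model.rank]
        expected = np.cumsum(lam) / lam.sum() * 100.0
        got = np.array([c for _, c, _ in information_curve(model)])
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_dominant_mode(self, rng):
        dim = 3 * int(np.prod(GRID))
        u1, u2 = np.linalg.qr(rng.normal(size=(dim, 2)))[0].T
        amps = rng.normal(size=8)
        dvfs = [dvf_from_flat(a * u1 * 100 + rng.normal() * u2) for a in amps]
        model = fit_pca(dvfs, k=1)
        assert information_curve(model)[0][1] >= 99.0

    def test_terminates_at_100(self, rng):
        model = fit_pca(random_stack(rng, 7), k=2)
        assert abs(information_curve(model)[-1][1] - 100.0) < 1e-6

    def test_equal_eigenvalue_modes(self, rng):
        dim = 3 * int(np.prod(GRID))
        Q = np.linalg.qr(rng.normal(size=(dim, 4)))[0].T
        # orthogonal +/- pairs per mode: equal variance, zero mean
        dvfs = []
        for s in (1.0, -1.0):
            for m in range(4):
                dvfs.append(dvf_from_flat(s * Q[m]))
        model = fit_pca(dvfs, k=4)
        got = [c for _, c, _ in information_curve(model)]
        np.testing.assert_allclose(got, [25.0, 50.0, 75.0, 100.0], atol=1e-8)


class TestSynthesizeProject:
    def test_zero_coefficients_give_mean(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        rec = synthesize_dvf(model, np.zeros(3))
        np.testing.assert_allclose(rec.flatten(), model.mean_dvf, atol=1e-12)

    def test_projection_of_mean_is_zero(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        q = project_dvf(model, dvf_from_flat(model.mean_dvf))
        np.testing.assert_allclose(q.q, 0.0, atol=1e-8)

    def test_unit_mode_projection(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        d = dvf_from_flat(model.mean_dvf + 5.0 * model.components[0])
        np.testing.assert_allclose(project_dvf(model, d).q, [5.0, 0.0, 0.0], atol=1e-8)

    def test_linearity(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        q = rng.normal(size=3)
        s1 = synthesize_dvf(model, q).flatten()
        s2 = synthesize_dvf(model, 2 * q).flatten()
        s0 = synthesize_dvf(model, np.zeros(3)).flatten()
        np.testing.assert_allclose(s2 - s1, s1 - s0, atol=1e-8)

    def test_projection_matches_lstsq_oracle(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        d = dvf_from_flat(rng.normal(size=3 * int(np.prod(GRID))))
        q = project_dvf(model, d).q
        A = model.components[:3].T
        q_ref, *_ = np.linalg.lstsq(A, d.flatten() - model.mean_dvf, rcond=None)
        np.testing.assert_allclose(q, q_ref, atol=1e-6)

    def test_wrong_length_rejected(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        with pytest.raises(ValueError):
            synthesize_dvf(model, np.zeros(5))


class TestSampleCoefficients:
    def phases(self, rng, n=10):
        return rng.normal(scale=[100.0, 10.0, 1.0], size=(n, 3))

    def test_zero_expansion_within_bounds(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        P = self.phases(rng)
        samples = sample_coefficients(
            model, P, SamplingSpec(n_samples=500, expansion=0.0, seed=3)
        )
        Q = np.stack([s.q for s in samples])
        assert np.all(Q >= P.min(0) - 1e-12) and np.all(Q <= P.max(0) + 1e-12)

    def test_900_samples_reproducible_within_expanded_bounds(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        P = self.phases(rng)
        spec = SamplingSpec(n_samples=900, expansion=0.15, seed=42)
        Q1 = np.stack([s.q for s in sample_coefficients(model, P, spec)])
        Q2 = np.stack([s.q for s in sample_coefficients(model, P, spec)])
        np.testing.assert_array_equal(Q1, Q2)
        R = P.max(0) - P.min(0)
        assert Q1.shape == (900, 3)
        assert np.all(Q1 >= P.min(0) - 0.15 * R) and np.all(Q1 <= P.max(0) + 0.15 * R)

    def test_empirical_bounds_converge(self, rng):
        """Monte-Carlo check of the uniform law on the expanded box."""
        model = fit_pca(random_stack(rng, 6), k=3)
        P = self.phases(rng)
        spec = SamplingSpec(n_samples=100_000, expansion=0.15, seed=9)
        Q = np.stack([s.q for s in sample_coefficients(model, P, spec)])
        R = P.max(0) - P.min(0)
        np.testing.assert_allclose(Q.min(0), P.min(0) - 0.15 * R, atol=0.01 * R.max())
        for j in range(3):
            assert abs(Q[:, j].min() - (P.min(0)[j] - 0.15 * R[j])) < 0.01 * R[j]
            assert abs(Q[:, j].max() - (P.max(0)[j] + 0.15 * R[j])) < 0.01 * R[j]

    def test_degenerate_motion_rejected(self, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        P = np.ones((5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            sample_coefficients(model, P, SamplingSpec(n_samples=10))


class TestWarpVolume:
    def volume(self, values):
        return Volume3D(values=values, spacing=SPACING, origin=ORIGIN)

    def zero_dvf(self):
        return dvf_from_flat(np.zeros(3 * int(np.prod(GRID))))

    def test_zero_dvf_identity(self, rng):
        vol = self.volume(rng.random(GRID))
        out = warp_volume(vol, self.zero_dvf())
        np.testing.assert_array_equal(out.values, vol.values)

    def test_integer_shift(self, rng):
        vol = self.volume(rng.random(GRID))
        d = np.zeros(GRID + (3,))
        d[..., 0] = 2 * SPACING[0]          # sample 2 voxels towards +x
        out = warp_volume(vol, DVFVolume(d, SPACING, ORIGIN))
        np.testing.assert_allclose(out.values[:6], vol.values[2:], atol=1e-12)

    def test_linear_ramp_constant_displacement(self):
        """Interpolating a linear ramp under constant displacement is exact."""
        x = np.arange(GRID[0], dtype=float)
        vol = self.volume(np.broadcast_to(x[:, None, None], GRID).copy())
        d = np.zeros(GRID + (3,))
        d[..., 0] = 1.5 * SPACING[0]
        out = warp_volume(vol, DVFVolume(d, SPACING, ORIGIN))
        expected = np.broadcast_to((x + 1.5)[:, None, None], GRID)
        np.testing.assert_allclose(out.values[:6], expected[:6], atol=1e-6)

    def test_grid_mismatch_rejected(self, rng):
        vol = Volume3D(np.zeros((4, 4, 4)), SPACING, ORIGIN)
        with pytest.raises(ValueError):
            warp_volume(vol, self.zero_dvf())


class TestModelSerialization:
    def test_round_trip(self, tmp_path, rng):
        model = fit_pca(random_stack(rng, 6), k=3)
        path = tmp_path / "model.npz"
        model.save(path)
        back = PCAMotionModel.load(path)
        np.testing.assert_array_equal(back.mean_dvf, model.mean_dvf)
        np.testing.assert_array_equal(back.components, model.components)
        assert back.k == model.k and back.grid_dims == model.grid_dims
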