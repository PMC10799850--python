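"""TV proximal map, monotone FISTA, traction inversion, deconvolution."""

import numpy as np
import pytest

from ritfm.elastic import sample_greens_kernel, forward_displacement
from ritfm.fields import DisplacementField, TractionField
from ritfm.solver import (
    DECONV_STAGE1,
    DECONV_STAGE2,
    FISTAConfig,
    deconvolve_volume,
    fista_solve,
    local_patch_traction,
    reconstruct_traction,
    total_variation,
    tv_prox,
)
from ritfm.synthetic import PhantomSpec, TractionPhantom, make_bead_phantom, \
    make_traction_phantom
from ritfm.volume import Volume


def taut_string_tv1d(y, lam):
    """Exact 1D TV denoiser (Condat's direct taut-string algorithm)."""
    y = np.asarray(y, float)
    n = len(y)
    x = np.empty(n)
    k = k0 = km = kp = 0
    vmin, vmax = y[0] - lam, y[0] + lam
    umin, umax = lam, -lam
    while True:
        if k == n - 1:
            x[k] = vmin + umin
            break
        if y[k + 1] + umin < vmin - lam:
            x[k0:km + 1] = vmin
            k = k0 = km = kp = km + 1
            vmin, vmax = y[k], y[k] + 2 * lam
            umin, umax = lam, -lam
        elif y[k + 1] + umax > vmax + lam:
            x[k0:kp + 1] = vmax
            k = k0 = km = kp = kp + 1
            vmin, vmax = y[k] - 2 * lam, y[k]
            umin, umax = lam, -lam
        else:
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin, km = lam, k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax, kp = -lam, k
        if k == n - 1:
            if umin < 0:
                x[k0:km + 1] = vmin
                k = k0 = km = km + 1
                vmin, umin, umax = y[k], lam, y[k] + lam - vmax
            elif umax > 0:
                x[k0:kp + 1] = vmax
                k = k0 = kp = kp + 1
                vmax, umax, umin = y[k], -lam, y[k] - lam - vmin
            else:
                x[k0:n] = vmin + umin / (k - k0 + 1)
                break
    return x


def make_plane_field(u, spacing):
    """Displacement field container from a (nplanes, ny, nx, 3) array."""
    nd, ny, nx = u.shape[:3]
    coords = np.zeros_like(u)
    Y, X = np.meshgrid(np.arange(ny) * spacing[1], np.arange(nx) * spacing[2],
                       indexing="ij")
    for i in range(nd):
        coords[i, ..., 0] = X
        coords[i, ..., 1] = Y
        coords[i, ..., 2] = (i + 1.5) * spacing[0]
    return DisplacementField(
        u=u, coords=coords, valid=np.ones((nd, ny, nx), bool),
        quality=np.ones((nd, ny, nx)), spacing=spacing,
    )


class TestTVProx:
    def test_zero_weight_identity(self, rng):
        x = rng.normal(size=(9, 9))
        np.testing.assert_array_equal(tv_prox(x, 0.0, 10), x)

    def test_constant_unchanged(self):
        c = np.full((8, 8, 4), 2.5)
        np.testing.assert_allclose(tv_prox(c, 1.0, 50), c, atol=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 0.3])
    def test_matches_taut_string_in_1d(self, rng, lam):
        """Dual projection converges to the exact 1D TV prox."""
        y = np.concatenate([np.zeros(25), np.ones(25)]) + rng.normal(0, 0.2, 50)
        x = tv_prox(y, lam, inner_iterations=400)
        np.testing.assert_allclose(x, taut_string_tv1d(y, lam), atol=1e-3)

    def test_noise_reduced_step_preserved(self, rng):
        y = np.concatenate([np.zeros(40), np.ones(40)])
        noisy = y + rng.normal(0, 0.15, 80)
        den = tv_prox(noisy, 0.3, 200)
        assert np.var(den - y) < np.var(noisy - y)
        assert den[:30].mean() < 0.3 and den[50:].mean() > 0.7

    def test_nonnegativity_projection(self):
        x = np.array([[-1.0, 2.0], [3.0, -4.0]])
        assert tv_prox(x, 0.0, 1, nonnegativity=True).min() == 0.0


class TestFistaSolve:
    def test_identity_operator_returns_data(self, rng):
        data = rng.normal(size=(10, 10))
        x, rep = fista_solve(lambda v: v, lambda v: v, data,
                             FISTAConfig(step_size=0.9, tv_weight=0.0,
                                         inner_iterations=1,
                                         outer_iterations=200))
        assert np.abs(x - data).max() < 1e-8
        assert rep.monotone

    def test_small_quadratic_matches_normal_equations(self, rng):
        """tau=0 least squares agrees with the dense solver to 1e-6."""
        A = rng.normal(size=(12, 7))
        b = rng.normal(size=12)
        L = np.linalg.norm(A, 2) ** 2
        x, _ = fista_solve(lambda v: A @ v, lambda v: A.T @ v, b,
                           FISTAConfig(step_size=0.95 / L, tv_weight=0.0,
                                       inner_iterations=1,
                                       outer_iterations=4000), x_shape=(7,))
        x_ref = np.linalg.solve(A.T @ A, A.T @ b)
        obj = lambda v: 0.5 * np.sum((A @ v - b) ** 2)
        assert obj(x) - obj(x_ref) < 1e-6

    def test_monotone_objective_trace(self, rng):
        """Objective trace is non-increasing on every problem configuration."""
        A = rng.normal(size=(20, 16))
        b = rng.normal(size=20)
        for tau in (0.0, 0.05, 0.5):
            _, rep = fista_solve(
                lambda v: A @ v, lambda v: A.T @ v, b,
                FISTAConfig(step_size=0.9 / np.linalg.norm(A, 2) ** 2,
                            tv_weight=tau, inner_iterations=30,
                            outer_iterations=150), x_shape=(16,))
            assert np.all(np.diff(rep.objective) <= 1e-12 * rep.objective[0])

    def test_bad_adjoint_rejected(self, rng):
        data = rng.normal(size=(5,))
        with pytest.raises(ValueError, match="dot-product"):
            fista_solve(lambda v: 2 * v, lambda v: 3 * v, data, FISTAConfig())

    def test_step_size_warning_above_lipschitz(self, rng):
        data = rng.normal(size=(6,))
        with pytest.warns(RuntimeWarning, match="1/L"):
            fista_solve(lambda v: 3 * v, lambda v: 3 * v, data,
                        FISTAConfig(step_size=0.5, tv_weight=0.0,
                                    inner_iterations=1, outer_iterations=2))

    def test_tau_zero_limit_approaches_least_squares(self, rng):
        A = rng.normal(size=(15, 10))
        b = rng.normal(size=15)
        x_ls = np.linalg.solve(A.T @ A, A.T @ b)
        L = np.linalg.norm(A, 2) ** 2
        dists = []
        for tau in (0.3, 0.1, 0.03, 0.0):
            x, _ = fista_solve(lambda v: A @ v, lambda v: A.T @ v, b,
                               FISTAConfig(step_size=0.9 / L, tv_weight=tau,
                                           inner_iterations=40,
                                           outer_iterations=800), x_shape=(10,))
            dists.append(np.linalg.norm(x - x_ls))
        assert all(d1 >= d2 - 1e-9 for d1, d2 in zip(dists, dists[1:]))


class TestTractionReconstruction:
    def test_zero_displacement_zero_traction(self, soft_substrate):
        f = make_plane_field(np.zeros((2, 8, 8, 3)), (1.5, 0.75, 0.75))
        t, rep = reconstruct_traction(f, soft_substrate)
        assert np.all(t.t == 0)
        assert rep.converged

    def test_noiseless_dipole_round_trip(self, soft_substrate):
        """Forward-model displacement inverts back to the injected dipole."""
        ny = nx = 24
        sp = 0.732
        ph = TractionPhantom(pattern="dipole", magnitude=100.0, extent=8.0)
        t_true = make_traction_phantom(ph, (ny, nx), (sp, sp))
        depths = (1.1, 1.83)
        k = sample_greens_kernel((ny, nx), (sp, sp), depths, soft_substrate)
        u = forward_displacement(t_true, k)
        f = make_plane_field(u, (0.73, sp, sp))
        f.coords[0, ..., 2] = depths[0]
        f.coords[1, ..., 2] = depths[1]
        t_rec, rep = reconstruct_traction(f, soft_substrate, FISTAConfig())
        corr = np.corrcoef(t_rec.t.ravel(), t_true.t.ravel())[0, 1]
        assert corr > 0.9
        net = t_rec.net_force()
        assert np.hypot(net[0], net[1]) < 0.05 * t_rec.gross_force()
        # TV shrinkage attenuates the peak; it must stay the right order
        ratio = np.abs(t_rec.t).max() / np.abs(t_true.t).max()
        assert 0.4 < ratio < 1.2
        assert np.all(np.diff(rep.objective) <= 1e-12 * rep.objective[0])

    def test_regularization_suppresses_noise_monotonically(self, soft_substrate):
        """Background traction std decreases as the TV weight grows."""
        sp = 0.732
        rng_local = np.random.default_rng(5)
        stds = {tau: [] for tau in (0.005, 0.02, 0.08)}
        for seed in range(3):
            noise = rng_local.normal(0, 1, size=(2, 16, 16, 3))
            noise[..., 2] *= 15.0 / 6.0
            u = noise * 6e-3  # 6 nm lateral / 15 nm axial, in um
            f = make_plane_field(u, (0.73, sp, sp))
            for tau in stds:
                cfg = FISTAConfig(tv_weight=tau, inner_iterations=50,
                                  outer_iterations=120)
                t, _ = reconstruct_traction(f, soft_substrate, cfg)
                stds[tau].append(t.t.std())
        means = [np.mean(stds[tau]) for tau in sorted(stds)]
        assert means[0] >= means[1] >= means[2]

    def test_local_patch_cross_check(self, soft_substrate):
        """The per-node least-squares mode localizes an isolated point load."""
        ny = nx = 12
        sp = 0.732
        t_true = np.zeros((ny, nx, 3))
        t_true[6, 6] = (80.0, 0.0, 0.0)
        k = sample_greens_kernel((ny, nx), (sp, sp), (1.1, 1.83),
                                 soft_substrate)
        u = forward_displacement(TractionField(t_true, (sp, sp)), k)
        f = make_plane_field(u, (0.73, sp, sp))
        f.coords[0, ..., 2] = 1.1
        f.coords[1, ..., 2] = 1.83
        t_loc = local_patch_traction(f, soft_substrate)
        peak = np.unravel_index(np.abs(t_loc.t[..., 0]).argmax(), (ny, nx))
        assert peak == (6, 6)


class TestDeconvolution:
    @staticmethod
    def _gaussian_psf(shape, sigma):
        zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2 for n in shape],
                                 indexing="ij")
        g = np.exp(-(zz ** 2 + yy ** 2 + xx ** 2) / (2 * sigma ** 2))
        return g / g.sum()

    def test_blur_round_trip_improves_rmse(self):
        spec = PhantomSpec(volume_shape=(24, 24, 24), voxel_pitch=(0.06,) * 3,
                           bead_contrast=0.1, background_level=0.0, seed=3)
        truth = make_bead_phantom(spec)
        psf = self._gaussian_psf((9, 9, 9), 2.0)
        from scipy.signal import fftconvolve

        blurred = truth.copy(data=fftconvolve(truth.data, psf, mode="same"))
        out, reports = deconvolve_volume(
            blurred, Volume(psf, truth.pitch), (DECONV_STAGE1, DECONV_STAGE2)
        )
        rmse_pre = np.sqrt(np.mean((blurred.data - truth.data) ** 2))
        rmse_post = np.sqrt(np.mean((out.data - truth.data) ** 2))
        assert rmse_post < rmse_pre
        for rep in reports:
            assert np.all(np.diff(rep.objective) <= 1e-12 * max(rep.objective[0], 1e-30))

    def test_deterministic(self):
        spec = PhantomSpec(volume_shape=(18, 18, 18), bead_contrast=0.1,
                           background_level=0.0, seed=4)
        vol = make_bead_phantom(spec)
        psf = Volume(self._gaussian_psf((7, 7, 7), 1.2), vol.pitch)
        a, _ = deconvolve_volume(vol, psf)
        b, _ = deconvolve_volume(vol, psf)
        np.testing.assert_array_equal(a.data, b.data)

    def test_psf_contracts(self):
        vol = Volume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError, match="unit sum"):
            deconvolve_volume(vol, Volume(np.ones((3, 3, 3)), (1, 1, 1)))
        with pytest.raises(ValueError, match="larger"):
            deconvolve_volume(vol, Volume(np.ones((9, 9, 9)) / 729.0, (1, 1, 1)))


def test_total_variation_of_constant_is_zero():
    assert total_variation(np.full((5, 5), 3.0)) == 0.0
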