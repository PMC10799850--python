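"""Subpixel window correlation and displacement-field estimation."""

import numpy as np
import pytest

from ritfm.elastic import forward_displacement, sample_greens_kernel
from ritfm.prep import CellMask
from ritfm.synthetic import (
    PhantomSpec,
    TractionPhantom,
    deform_phantom,
    make_bead_phantom,
    make_traction_phantom,
    translate_volume,
)
from ritfm.tracking import (
    TrackingConfig,
    estimate_displacement_field,
    field_stats,
    subpixel_shift,
)
from ritfm.fields import DisplacementField

PITCH = 0.183


def dense_correlation_shift(ref, mov, search=1.0, step=0.01):
    """Brute-force oracle: evaluate the cross-correlation on a dense subvoxel
    lattice around the integer peak via explicit Fourier phase shifts."""
    F = np.fft.fftn(ref) * np.conj(np.fft.fftn(mov))
    cc = np.fft.ifftn(F).real
    peak = np.array(np.unravel_index(cc.argmax(), cc.shape), float)
    peak[peak > np.array(ref.shape) / 2] -= np.array(ref.shape)[
        peak > np.array(ref.shape) / 2]
    freqs = [np.fft.fftfreq(n) for n in ref.shape]
    best, best_val = None, -np.inf
    grid = np.arange(-search, search + step / 2, step)
    for dz in grid + peak[0]:
        for dy in grid + peak[1]:
            for dx in grid + peak[2]:
                ramp = np.exp(
                    2j * np.pi * (
                        freqs[0][:, None, None] * dz
                        + freqs[1][None, :, None] * dy
                        + freqs[2][None, None, :] * dx
                    )
                )
                val = (F * ramp).sum().real
                if val > best_val:
                    best_val, best = val, (dz, dy, dx)
    return -np.array(best)


class TestSubpixelShift:
    def test_identical_windows_zero(self, bead_volume_small):
        w = bead_volume_small.data[:32, :32, :32]
        shift, q = subpixel_shift(w, w)
        assert np.all(shift == 0)
        assert q > 0.9

    def test_integer_shift_exact(self, bead_volume_small):
        w = bead_volume_small.data
        mov = np.roll(w, (3, -2, 1), axis=(0, 1, 2))
        for up in (1, 10, 100):
            shift, _ = subpixel_shift(w, mov, upsample_factor=up)
            np.testing.assert_array_equal(shift, (3, -2, 1))

    def test_subvoxel_shift_matches_dense_oracle(self):
        """Upsampled refinement agrees with brute-force dense correlation."""
        vol = make_bead_phantom(PhantomSpec(volume_shape=(24, 24, 24), seed=5))
        true = (0.30, -0.20, 0.10)
        mov = translate_volume(vol, true).data
        shift, _ = subpixel_shift(vol.data, mov, upsample_factor=100)
        oracle = dense_correlation_shift(vol.data, mov, search=0.5, step=0.05)
        np.testing.assert_allclose(shift, true, atol=0.05)
        np.testing.assert_allclose(shift, oracle, atol=0.06)

    def test_flat_window_flagged_invalid(self):
        flat = np.zeros((8, 8, 8))
        shift, q = subpixel_shift(flat, flat)
        assert shift is None and q == 0.0


class TestDisplacementField:
    CFG = TrackingConfig(subset_size=24, grid_spacing=8, upsample_factor=50)

    def test_zero_deformation_zero_field(self, bead_volume_small):
        f = estimate_displacement_field(bead_volume_small,
                                        bead_volume_small.copy(), self.CFG)
        assert np.abs(f.u).max() < 1e-9
        assert f.n_valid == int(np.prod(f.grid_shape))

    def test_rigid_lateral_translation_recovered(self):
        """3-um lateral stage translation: mean ~3 um, std < 10 nm."""
        vol = make_bead_phantom(PhantomSpec(volume_shape=(80, 80, 80), seed=2))
        shift_vox = 3.0 / PITCH  # 16.4 voxels; window must exceed twice this
        mov = translate_volume(vol, (0, 0, shift_vox))
        cfg = TrackingConfig(subset_size=48, grid_spacing=11,
                             upsample_factor=100)
        f = estimate_displacement_field(vol, mov, cfg)
        st = field_stats(f, (3.0, 0.0, 0.0))
        assert abs(st["mean"][0] - 3.0) < 0.05 * PITCH
        assert max(st["std"]) < 0.010  # 10 nm in um

    def test_swap_negates_field(self, bead_volume_small):
        mov = translate_volume(bead_volume_small, (0.8, -0.4, 0.3))
        f1 = estimate_displacement_field(bead_volume_small, mov, self.CFG)
        f2 = estimate_displacement_field(mov, bead_volume_small, self.CFG)
        np.testing.assert_allclose(f1.u, -f2.u, atol=5e-3)

    def test_integer_shift_equivariance(self, bead_volume_small):
        """A global integer shift adds exactly to every recovered vector."""
        mov = translate_volume(bead_volume_small, (0.6, 0.0, 0.2))
        f1 = estimate_displacement_field(bead_volume_small, mov, self.CFG)
        mov2 = translate_volume(mov, (1, 0, -2), mode="integer")
        f2 = estimate_displacement_field(bead_volume_small, mov2, self.CFG)
        delta = f2.u - f1.u
        # exact up to window edge effects (a few hundredths of a voxel)
        np.testing.assert_allclose(
            delta[..., 0].mean(), -2 * PITCH, atol=0.015)
        np.testing.assert_allclose(
            delta[..., 2].mean(), -1 * PITCH, atol=0.015)

    def test_elastic_scene_matches_continuum_field(self, bead_volume_flat,
                                                   soft_substrate):
        """Deform -> track recovers the forward-model field, RMSE < 0.1 vox."""
        ph = TractionPhantom(pattern="dipole", magnitude=100.0, extent=8.0)
        t = make_traction_phantom(ph, (96, 96), (PITCH, PITCH))
        mov = deform_phantom(bead_volume_flat, t, soft_substrate)
        cfg = TrackingConfig(subset_size=12, grid_spacing=4,
                             upsample_factor=20, min_peak_quality=0.05)
        f = estimate_displacement_field(bead_volume_flat, mov, cfg)
        depths = np.unique(f.coords[..., 2])[:2]
        k = sample_greens_kernel((96, 96), (PITCH, PITCH), depths,
                                 soft_substrate)
        u_true = forward_displacement(t, k)
        ix = (f.coords[0, 0, :, 0] / PITCH).round().astype(int)
        iy = (f.coords[0, :, 0, 1] / PITCH).round().astype(int)
        err = f.u[:2] - u_true[:, iy][:, :, ix]
        rmse_vox = np.sqrt((err ** 2).mean()) / PITCH
        assert rmse_vox < 0.1

    def test_masked_windows_invalid_and_infilled(self, bead_volume_small):
        mask = np.zeros(bead_volume_small.shape, bool)
        mask[:, :20, :20] = True  # cell corner
        mov = translate_volume(bead_volume_small, (0.5, 0.5, 0.5))
        f = estimate_displacement_field(
            bead_volume_small, mov, self.CFG, CellMask(mask))
        assert f.n_valid < int(np.prod(f.grid_shape))
        assert np.all(np.isfinite(f.u))  # invalid nodes infilled

    def test_too_few_valid_windows_raises(self, bead_volume_small):
        mask = np.ones(bead_volume_small.shape, bool)
        mask[:, -1, -1] = False
        with pytest.raises(ValueError):
            estimate_displacement_field(
                bead_volume_small,
                bead_volume_small.copy(),
                self.CFG,
                CellMask(mask),
            )


class TestFieldStats:
    @staticmethod
    def _field(u):
        shp = u.shape[:3]
        return DisplacementField(
            u=u, coords=np.zeros(u.shape), valid=np.ones(shp, bool),
            quality=np.ones(shp), spacing=(1, 1, 1))

    def test_identical_fields_zero_rmse(self, rng):
        u = rng.normal(size=(3, 5, 5, 3))
        st = field_stats(self._field(u), self._field(u))
        assert np.allclose(st["rmse"], 0)

    def test_rmse_recovers_noise_sigma_large_sample(self, rng):
        """With >2700 nodes, per-axis RMSE matches sigma within 5%."""
        shape = (3, 31, 31)  # 2883 nodes
        sigma = np.array([0.006, 0.006, 0.015])
        u = rng.normal(0, sigma, size=shape + (3,))
        st = field_stats(self._field(u), 0.0)
        assert st["n"] > 2700
        np.testing.assert_allclose(st["rmse"], sigma, rtol=0.05)

    def test_no_valid_nodes_raises(self, rng):
        f = self._field(rng.normal(size=(2, 3, 3, 3)))
        f.valid[:] = False
        with pytest.raises(ValueError):
            field_stats(f, 0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        TrackingConfig(subset_size=8, grid_spacing=9)
    with pytest.raises(ValueError):
        TrackingConfig(upsample_factor=0)
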