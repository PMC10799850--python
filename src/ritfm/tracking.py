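"""Windowed 3D digital volume correlation with subpixel refinement.

The displacement field between a reference (relaxed) and a deformed volume is
estimated one tracking window at a time: the full 3D cross-correlation of the
window pair gives the integer-voxel peak, and a localized upsampled discrete
Fourier transform around that peak refines it to ``1/upsample_factor`` of a
voxel (single-step subpixel image registration).  Windows are laid out on a
regular grid — the defaults, a 64-voxel subset on an 11-voxel spacing, match
the tomogram scale of 0.183 um/voxel (an 11.7-um subset on a 2-um grid).

Windows with too few unmasked voxels, no contrast, an implausibly large
vector, or a weak correlation peak are flagged invalid and infilled by linear
interpolation from their valid neighbours so the traction inversion receives
a complete grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata
from skimage.registration import phase_cross_correlation

from .fields import DisplacementField
from .prep import CellMask, dilate_mask
from .volume import Volume

__all__ = ["TrackingConfig", "subpixel_shift", "estimate_displacement_field",
           "field_stats"]


@dataclass(frozen=True)
class TrackingConfig:
    """Digital volume correlation parameters.

    ``subset_size``: tracking-window edge in voxels (default 64).
    ``grid_spacing``: node spacing in voxels (default 11).
    ``upsample_factor``: subpixel refinement factor (default 100, i.e. 0.01
    voxel).  ``min_valid_fraction``: minimum unmasked fraction per window.
    ``min_peak_quality``: windows with a weaker normalized correlation peak
    are flagged invalid.
    """

    subset_size: int = 64
    grid_spacing: int = 11
    upsample_factor: int = 100
    min_valid_fraction: float = 0.5
    min_peak_quality: float = 0.1

    def __post_init__(self) -> None:
        if self.subset_size <= self.grid_spacing:
            raise ValueError("subset_size must exceed grid_spacing")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")


def subpixel_shift(ref_win: np.ndarray, mov_win: np.ndarray,
                   upsample_factor: int = 100):
    """Subpixel displacement of ``mov_win`` relative to ``ref_win`` (voxels).

    Full cross-correlation locates the integer peak; a matrix-multiply DFT
    upsampled around it refines the estimate.  Returns ``(shift, quality)``
    with shift in array axis order and quality in ``[0, 1]``
    (1 − translation-invariant normalized RMS error); a flat window returns
    ``(None, 0.0)`` rather than raising.
    """
    ref_win = np.asarray(ref_win, dtype=float)
    mov_win = np.asarray(mov_win, dtype=float)
    if ref_win.shape != mov_win.shape:
        raise ValueError("windows must have the same shape")
    if ref_win.std() == 0 or mov_win.std() == 0:
        return None, 0.0
    shift, error, _ = phase_cross_correlation(
        ref_win, mov_win, upsample_factor=upsample_factor, normalization=None
    )
    quality = float(np.clip(1.0 - error, 0.0, 1.0))
    # returned shift registers mov onto ref; displacement of mov is -shift
    return -shift, quality


def _node_positions(n: int, subset: int, spacing: int) -> np.ndarray:
    half = subset // 2
    last = n - (subset - half)
    if last < half:
        return np.array([], dtype=int)
    return np.arange(half, last + 1, spacing, dtype=int)


def estimate_displacement_field(
    ref: Volume,
    mov: Volume,
    cfg: TrackingConfig | None = None,
    mask: CellMask | None = None,
) -> DisplacementField:
    """Track the 3D displacement field between two preprocessed volumes.

    One vector per grid node at ``cfg.grid_spacing``; each is the subpixel
    cross-correlation shift of the ``subset_size`` window centred on the
    node, converted to physical micrometres in the package frame (x, y
    lateral; z positive upward, i.e. opposite the depth axis).  Invalid
    windows are infilled by linear interpolation from valid neighbours and
    flagged.  Raises if fewer than 4 windows are valid.
    """
    cfg = cfg or TrackingConfig()
    if ref.shape != mov.shape:
        raise ValueError("volumes must have the same shape")
    if ref.pitch != mov.pitch:
        raise ValueError("volumes must share a voxel pitch")
    nz, ny, nx = ref.shape
    s = cfg.subset_size
    centers = [_node_positions(n, s, cfg.grid_spacing) for n in (nz, ny, nx)]
    if any(c.size == 0 for c in centers):
        raise ValueError(
            f"subset size {s} does not fit in volume of shape {ref.shape}"
        )
    gz, gy, gx = centers
    shape_grid = (gz.size, gy.size, gx.size)

    invalid_vox = None
    if mask is not None:
        if mask.mask.shape != ref.shape:
            raise ValueError("mask incongruent with volumes")
        invalid_vox = dilate_mask(mask, s // 2).mask

    u_vox = np.full(shape_grid + (3,), np.nan)
    quality = np.zeros(shape_grid)
    valid = np.zeros(shape_grid, dtype=bool)
    half = s // 2
    ref_d = np.asarray(ref.data, dtype=float)
    mov_d = np.asarray(mov.data, dtype=float)

    for iz, cz in enumerate(gz):
        for iy, cy in enumerate(gy):
            for ix, cx in enumerate(gx):
                sl = (
                    slice(cz - half, cz - half + s),
                    slice(cy - half, cy - half + s),
                    slice(cx - half, cx - half + s),
                )
                if invalid_vox is not None:
                    frac = 1.0 - invalid_vox[sl].mean()
                    if frac < cfg.min_valid_fraction:
                        continue
                shift, q = subpixel_shift(
                    ref_d[sl], mov_d[sl], cfg.upsample_factor
                )
                if shift is None or q < cfg.min_peak_quality:
                    continue
                if np.any(np.abs(shift) >= s / 2):
                    continue
                u_vox[iz, iy, ix] = shift
                quality[iz, iy, ix] = q
                valid[iz, iy, ix] = True

    n_valid = int(valid.sum())
    if n_valid < 4:
        raise ValueError(f"only {n_valid} valid tracking windows (< 4)")

    if n_valid < valid.size:
        pts = np.argwhere(valid).astype(float)
        bad = np.argwhere(~valid).astype(float)
        for c in range(3):
            vals = u_vox[valid][:, c]
            if pts.shape[0] >= 4 and np.ptp(pts, axis=0).min() > 0:
                filled = griddata(pts, vals, bad, method="linear")
            else:
                filled = np.full(bad.shape[0], np.nan)
            nn = griddata(pts, vals, bad, method="nearest")
            filled = np.where(np.isnan(filled), nn, filled)
            u_vox[~valid, c] = filled

    dz, dy, dx = ref.pitch
    u_phys = np.empty_like(u_vox)
    u_phys[..., 0] = u_vox[..., 2] * dx          # ux
    u_phys[..., 1] = u_vox[..., 1] * dy          # uy
    u_phys[..., 2] = -u_vox[..., 0] * dz         # uz, positive upward

    Z, Y, X = np.meshgrid(gz * dz, gy * dy, gx * dx, indexing="ij")
    coords = np.stack([X, Y, Z], axis=-1)        # (x, y, depth) um
    return DisplacementField(
        u=u_phys,
        coords=coords,
        valid=valid,
        quality=quality,
        spacing=(cfg.grid_spacing * dz, cfg.grid_spacing * dy,
                 cfg.grid_spacing * dx),
        metadata={
            "subset_size": s,
            "grid_spacing": cfg.grid_spacing,
            "upsample_factor": cfg.upsample_factor,
            "n_valid": n_valid,
            "n_infilled": int(valid.size - n_valid),
        },
    )


def field_stats(field: DisplacementField, expected) -> dict:
    """Per-axis RMSE / mean / std of a field against an expected field.

    ``expected`` may be another congruent :class:`DisplacementField`, a
    constant 3-vector in micrometres, or 0.  Statistics run over valid nodes
    only; the node count is reported.
    """
    if isinstance(expected, DisplacementField):
        if expected.grid_shape != field.grid_shape:
            raise ValueError("grids incongruent")
        exp = expected.u
    else:
        exp = np.broadcast_to(np.asarray(expected, dtype=float), field.u.shape)
    v = field.valid
    n = int(v.sum())
    if n == 0:
        raise ValueError("no valid nodes")
    err = field.u[v] - exp[v]
    return {
        "n": n,
        "rmse": tuple(np.sqrt((err ** 2).mean(axis=0))),
        "mean": tuple(field.u[v].mean(axis=0)),
        "std": tuple(field.u[v].std(axis=0)),
        "mean_error": tuple(err.mean(axis=0)),
    }
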