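"""Tomogram pre-processing: 3D high-pass filtering, masking, registration.

The tracking pipeline expects its inputs in a fixed order — high-pass filter,
then cell-region mask, then global registration — so that only the
bead-scale signal drives the correlation.  The high-pass filter is a
zero-sum, Gaussian-minus-mean kernel on an anisotropic support (lateral
window 500 nm, axial 1 um by default): the Gaussian passes the sub-resolution
bead spots while the subtracted mean removes the DC component and the smooth
cellular/optical background.  Global registration removes rigid drift
between the paired tomograms with a Fourier-transform-based subpixel
correlation, leaving only the locally varying elastic deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .volume import Volume

__all__ = [
    "HighPassKernelSpec",
    "CellMask",
    "build_highpass_kernel",
    "highpass_filter",
    "apply_mask",
    "dilate_mask",
    "global_register",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class HighPassKernelSpec:
    """High-pass kernel windows in physical units.

    ``w_xy`` and ``w_z`` are the lateral and axial window half-sizes in
    micrometres (defaults 0.5 um and 1 um); ``voxel_pitch`` is ``(dz, dy,
    dx)`` in micrometres.  The Gaussian width is fixed at ``sigma = sqrt 2``
    voxels (``exp(-(i^2+j^2+k^2)/4)``).
    """

    w_xy: float = 0.5
    w_z: float = 1.0
    voxel_pitch: tuple[float, float, float] = (0.183, 0.183, 0.183)

    def __post_init__(self) -> None:
        if self.w_xy <= 0 or self.w_z <= 0:
            raise ValueError("window sizes must be positive")

    @property
    def window_voxels(self) -> tuple[int, int, int]:
        """Half-window in voxels per axis (z, y, x), rounded half-up."""
        dz, dy, dx = self.voxel_pitch
        wz = _round_half_up(self.w_z / dz)
        wy = _round_half_up(self.w_xy / dy)
        wx = _round_half_up(self.w_xy / dx)
        if min(wz, wy, wx) < 1:
            raise ValueError(
                f"window smaller than one voxel at pitch {self.voxel_pitch}"
            )
        return wz, wy, wx


def build_highpass_kernel(spec: HighPassKernelSpec) -> np.ndarray:
    """Zero-sum Gaussian-minus-mean kernel on a ``(2wz+1, 2wy+1, 2wx+1)`` support.

    The unit-sum Gaussian part minus the flat mean ``1/N`` makes the weights
    sum to exactly zero (constant volumes map to zero) while keeping the
    central weight positive, i.e. a bead-scale band-pass with DC removal.
    """
    wz, wy, wx = spec.window_voxels
    zz = np.arange(-wz, wz + 1)[:, None, None]
    yy = np.arange(-wy, wy + 1)[None, :, None]
    xx = np.arange(-wx, wx + 1)[None, None, :]
    g = np.exp(-(zz ** 2 + yy ** 2 + xx ** 2) / 4.0)
    g /= g.sum()
    kernel = g - 1.0 / g.size
    kernel -= kernel.sum() / kernel.size  # exact zero sum to rounding
    return kernel


def highpass_filter(vol: Volume, spec: HighPassKernelSpec | None = None) -> Volume:
    """Apply the 3D high-pass kernel with reflect boundary handling."""
    spec = spec or HighPassKernelSpec(voxel_pitch=vol.pitch)
    kernel = build_highpass_kernel(spec)
    out = ndimage.convolve(np.asarray(vol.data, dtype=float), kernel, mode="reflect")
    return vol.copy(data=out, highpass=(spec.w_xy, spec.w_z))


@dataclass
class CellMask:
    """Boolean cell-region mask congruent with a volume (True = cell voxels).

    ``provenance`` records how the mask was made: ``manual_box``,
    ``threshold`` or ``external``.
    """

    mask: np.ndarray
    provenance: str = "external"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.provenance not in {"manual_box", "threshold", "external"}:
            raise ValueError(f"unknown mask provenance {self.provenance!r}")

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())

    @classmethod
    def axial_above(cls, shape, z0: int) -> "CellMask":
        """Mask every voxel with z index > z0 (axial removal of the cell)."""
        m = np.zeros(shape, dtype=bool)
        m[z0 + 1:] = True
        return cls(m, provenance="manual_box", metadata={"z0": z0})

    @classmethod
    def box(cls, shape, lo, hi) -> "CellMask":
        """Rectangular mask over voxel index ranges ``lo[i]:hi[i]``."""
        m = np.zeros(shape, dtype=bool)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return cls(m, provenance="manual_box")


def apply_mask(vol: Volume, mask: CellMask, fill: str = "background") -> Volume:
    """Replace masked (cell) voxels by a fill value.

    ``fill='zero'`` writes zeros; ``fill='background'`` writes the median of
    the unmasked voxels.  Raises if the mask covers more than 90% of the
    volume (nothing left to track).
    """
    if mask.mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.mask.shape} != volume shape {vol.shape}")
    cov = mask.coverage
    if cov > 0.9:
        raise ValueError(f"mask covers {cov:.0%} of the volume; nothing left to track")
    if fill == "zero":
        value = 0.0
    elif fill == "background":
        value = float(np.median(vol.data[~mask.mask])) if cov < 1.0 else 0.0
    else:
        raise ValueError(f"unknown fill mode {fill!r}")
    out = np.asarray(vol.data, dtype=float).copy()
    out[mask.mask] = value
    return vol.copy(data=out, mask_coverage=cov, mask_fill=fill)


def dilate_mask(mask: CellMask, radius_vox: int) -> CellMask:
    """Binary-dilate the mask by a cubic structuring element of given radius.

    Used before window-validity counting so cell-edge signal cannot leak into
    windows treated as gel-only.
    """
    if radius_vox <= 0:
        return CellMask(mask.mask.copy(), mask.provenance, dict(mask.metadata))
    size = 2 * radius_vox + 1
    dil = ndimage.binary_dilation(mask.mask, structure=np.ones((size,) * 3, bool))
    return CellMask(dil, mask.provenance, {**mask.metadata, "dilated_vox": radius_vox})


def global_register(
    ref: Volume,
    mov: Volume,
    upsample_factor: int = 100,
    min_correlation: float = 0.05,
) -> tuple[np.ndarray, Volume]:
    """Estimate and remove one global rigid translation between two volumes.

    Returns the estimated shift of ``mov`` relative to ``ref`` in voxels
    (axis order z, y, x) and the re-registered moving volume (the inverse
    shift applied by exact Fourier translation).  Raises if the registered
    correlation is below ``min_correlation`` (non-overlapping content).
    """
    if ref.shape != mov.shape:
        raise ValueError("volumes must have the same shape")
    a = np.asarray(ref.data, dtype=float)
    b = np.asarray(mov.data, dtype=float)
    shift, _, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization=None
    )
    # phase_cross_correlation returns the shift that maps mov onto ref; the
    # displacement of mov relative to ref is its negative
    from .synthetic import translate_volume

    registered = translate_volume(mov, shift, mode="fourier")
    ra = a - a.mean()
    rb = registered.data - registered.data.mean()
    denom = np.linalg.norm(ra) * np.linalg.norm(rb)
    corr = float((ra * rb).sum() / denom) if denom > 0 else 0.0
    if corr < min_correlation:
        raise ValueError(
            f"registration correlation {corr:.3f} below {min_correlation}; "
            "volumes share no content"
        )
    if np.any(np.abs(shift) > 0.25 * np.array(ref.shape)):
        warnings.warn("large global drift; check acquisition", RuntimeWarning,
                      stacklevel=2)
    return -shift, registered
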