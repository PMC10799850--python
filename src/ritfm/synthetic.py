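"""Synthetic bead-gel scenes: phantoms, ground-truth tractions, forward warps.

This module emulates what the instrument sees so that every downstream stage
(filtering, registration, tracking, inversion) can be validated against known
ground truth.  The defaults reproduce the study conditions: 200-nm
polystyrene beads seeded at three per cubic micrometre in a polyacrylamide
gel, imaged at a voxel pitch of 0.183 um with a resolution of 161 nm lateral
and 401 nm axial.  Beads are rendered as PSF-blurred Gaussian spots (the
beads are below the resolution limit), the bead count is Poisson-sampled from
the seeding density, and every generator is a pure function of its
specification plus a seed.

Ground-truth traction patterns (force dipole, contractile ring, normal-load
patch, rotational moment) mimic the inward-shear / distal-up-proximal-down
structure of adherent-cell tractions; :func:`deform_phantom` pushes them
through the elastic forward model and warps the relaxed volume accordingly,
producing the "under traction" member of an imaging pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .elastic import ElasticSubstrate, forward_displacement, sample_greens_kernel
from .fields import TractionField
from .volume import Volume

__all__ = [
    "PhantomSpec",
    "TractionPhantom",
    "NoiseSpec",
    "make_bead_phantom",
    "translate_volume",
    "make_traction_phantom",
    "deform_phantom",
    "add_noise",
]

# tomogram resolution (um); bead spots are rendered with sigma = FWHM / 2.355,
# floored at 0.75 voxel so the spots stay representable on the sampling grid
RESOLUTION_LATERAL_UM = 0.161
RESOLUTION_AXIAL_UM = 0.401
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Bead-seeded gel phantom specification.

    ``volume_shape`` is ``(nz, ny, nx)`` voxels; ``voxel_pitch`` is
    ``(dz, dy, dx)`` in micrometres.  ``bead_density`` is beads per cubic
    micrometre (default 3.0); ``bead_diameter`` in micrometres (default 0.2,
    i.e. 200-nm polystyrene spheres).  ``bead_contrast`` is the dimensionless
    RI excess of a rendered spot peak over the background.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_pitch: tuple[float, float, float] = (0.183, 0.183, 0.183)
    bead_density: float = 3.0
    bead_diameter: float = 0.2
    bead_contrast: float = 0.05
    background_level: float = 1.337
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_density < 0:
            raise ValueError("bead_density must be non-negative")
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        if any(n < 1 for n in self.volume_shape) or any(
            p <= 0 for p in self.voxel_pitch
        ):
            raise ValueError("volume shape and pitch must be positive")

    @property
    def physical_volume_um3(self) -> float:
        return float(
            np.prod([n * p for n, p in zip(self.volume_shape, self.voxel_pitch)])
        )

    @property
    def expected_bead_count(self) -> float:
        return self.bead_density * self.physical_volume_um3


@dataclass(frozen=True)
class TractionPhantom:
    """Ground-truth traction pattern.

    ``pattern`` is one of ``dipole`` (two opposing in-plane Gaussian patches,
    balanced), ``ring`` (inward radial shear on an annulus, balanced),
    ``patch`` (normal load: upward at a distal annulus, downward at the
    proximal disc, balanced), or ``rotational_moment`` (azimuthal shear ring,
    zero net force, finite torque).  ``magnitude`` is the peak traction in
    pascal; ``center`` and ``extent`` are in micrometres; ``orientation`` is
    the in-plane unit vector of the dipole axis.
    """

    pattern: str = "dipole"
    magnitude: float = 100.0
    center: tuple[float, float] = (0.0, 0.0)   # relative to grid centre, um
    extent: float = 8.0
    patch_sigma: float = 2.5
    orientation: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.pattern not in {"dipole", "ring", "patch", "rotational_moment"}:
            raise ValueError(f"unknown traction pattern {self.pattern!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive imaging / displacement noise levels (both Gaussian, seeded)."""

    additive_sigma: float = 0.0
    displacement_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sigma < 0 or any(s < 0 for s in self.displacement_sigma):
            raise ValueError("noise sigmas must be non-negative")


def _bead_sigmas_vox(spec: PhantomSpec) -> np.ndarray:
    sig_um = np.array(
        [
            RESOLUTION_AXIAL_UM * _FWHM_TO_SIGMA,
            RESOLUTION_LATERAL_UM * _FWHM_TO_SIGMA,
            RESOLUTION_LATERAL_UM * _FWHM_TO_SIGMA,
        ]
    )
    sig_vox = sig_um / np.asarray(spec.voxel_pitch)
    return np.maximum(sig_vox, 0.75)


def _bandlimit(data: np.ndarray) -> np.ndarray:
    """Zero the unpaired Nyquist planes of even-sized axes.

    Subvoxel Fourier translation of a real volume is exactly invertible only
    when the (Hermitian-unpaired) Nyquist bins carry no energy; rendered
    phantoms are therefore strictly band-limited below Nyquist.
    """
    f = np.fft.fftn(data)
    for ax, n in enumerate(data.shape):
        if n % 2 == 0:
            sl = [slice(None)] * data.ndim
            sl[ax] = n // 2
            f[tuple(sl)] = 0.0
    return np.fft.ifftn(f).real


def make_bead_phantom(spec: PhantomSpec) -> Volume:
    """Render a bead-seeded gel volume.

    The bead count is Poisson-sampled from ``density x physical volume``;
    positions are uniform at subvoxel precision; each bead adds a Gaussian
    spot whose width reflects the PSF-blurred 200-nm bead.  Bit-identical for
    equal specifications.
    """
    extent_um = [n * p for n, p in zip(spec.volume_shape, spec.voxel_pitch)]
    if spec.bead_density > 0 and min(extent_um) < spec.bead_diameter:
        raise ValueError(
            f"physical volume {extent_um} um too small to contain one "
            f"{spec.bead_diameter}-um bead"
        )
    rng = np.random.default_rng(spec.seed)
    n_beads = int(rng.poisson(spec.expected_bead_count)) if spec.bead_density > 0 else 0
    data = np.full(spec.volume_shape, spec.background_level, dtype=np.float64)
    sig = _bead_sigmas_vox(spec)
    half = np.ceil(4.0 * sig).astype(int)
    shape = np.array(spec.volume_shape)
    positions = rng.uniform(0.0, 1.0, size=(n_beads, 3)) * shape  # voxel coords
    for pos in positions:
        lo = np.maximum(np.floor(pos - half).astype(int), 0)
        hi = np.minimum(np.floor(pos + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz = np.arange(lo[0], hi[0])[:, None, None]
        yy = np.arange(lo[1], hi[1])[None, :, None]
        xx = np.arange(lo[2], hi[2])[None, None, :]
        g = np.exp(
            -0.5
            * (
                ((zz - pos[0]) / sig[0]) ** 2
                + ((yy - pos[1]) / sig[1]) ** 2
                + ((xx - pos[2]) / sig[2]) ** 2
            )
        )
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += spec.bead_contrast * g
    if n_beads:
        data = _bandlimit(data)
    return Volume(
        data,
        spec.voxel_pitch,
        metadata={
            "generator": "make_bead_phantom",
            "n_beads": n_beads,
            "seed": spec.seed,
            "bead_density": spec.bead_density,
        },
    )


def translate_volume(vol: Volume, shift, mode: str = "fourier") -> Volume:
    """Rigidly translate a volume by ``shift`` voxels, axis order ``(z, y, x)``.

    ``integer`` mode rolls the grid (periodic boundary, exact); ``fourier``
    mode applies an exact band-limited subvoxel shift via the FFT phase ramp
    (also periodic, volume sum preserved to rounding error).
    """
    shift = np.asarray(shift, dtype=float)
    if shift.shape != (3,) or not np.all(np.isfinite(shift)):
        raise ValueError(f"shift must be a finite 3-vector, got {shift}")
    if np.any(np.abs(shift) >= np.array(vol.shape)):
        raise ValueError("shift exceeds the volume extent")
    if mode == "integer":
        if not np.allclose(shift, np.round(shift)):
            raise ValueError("integer mode requires whole-voxel shifts")
        out = np.roll(vol.data, np.round(shift).astype(int), axis=(0, 1, 2))
    elif mode == "fourier":
        f = np.fft.fftn(np.asarray(vol.data, dtype=float))
        out = np.fft.ifftn(ndimage.fourier_shift(f, shift)).real
    else:
        raise ValueError(f"unknown translation mode {mode!r}")
    return vol.copy(data=out, translated_by_vox=tuple(shift))


def _surface_grids(grid_shape, pitch):
    ny, nx = grid_shape
    dy, dx = pitch
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    return np.meshgrid(y, x, indexing="ij")


def make_traction_phantom(
    phantom: TractionPhantom,
    grid_shape: tuple[int, int],
    pitch: tuple[float, float],
) -> TractionField:
    """Render a ground-truth traction pattern on a surface grid.

    Balanced patterns (dipole, ring, patch) integrate to zero net force by
    construction.  ``grid_shape`` is ``(ny, nx)``; ``pitch`` is ``(dy, dx)``
    in micrometres.
    """
    Y, X = _surface_grids(grid_shape, pitch)
    cy, cx = phantom.center[1], phantom.center[0]
    extent = phantom.extent
    half_diag = float(np.hypot(Y.max() - Y.min(), X.max() - X.min())) / 2.0
    if extent > 2.0 * half_diag:
        raise ValueError(f"pattern extent {extent} um does not fit the grid")
    t = np.zeros(grid_shape + (3,))
    m = phantom.magnitude
    s = phantom.patch_sigma
    if m == 0:
        return TractionField(t, pitch, metadata={"pattern": phantom.pattern})

    if phantom.pattern == "dipole":
        ox, oy = phantom.orientation
        n = np.hypot(ox, oy)
        ox, oy = ox / n, oy / n
        # two patches at +/- extent/2 along the orientation, pulling inward
        for sgn in (+1.0, -1.0):
            px = cx + sgn * ox * extent / 2.0
            py = cy + sgn * oy * extent / 2.0
            g = np.exp(-(((X - px) ** 2 + (Y - py) ** 2) / (2.0 * s * s)))
            t[..., 0] += -sgn * ox * m * g
            t[..., 1] += -sgn * oy * m * g
    elif phantom.pattern == "ring":
        r = np.hypot(X - cx, Y - cy)
        band = np.exp(-((r - extent / 2.0) ** 2) / (2.0 * s * s))
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r > 0, (X - cx) / r, 0.0)
            uy = np.where(r > 0, (Y - cy) / r, 0.0)
        t[..., 0] = -m * band * ux  # inward radial shear
        t[..., 1] = -m * band * uy
    elif phantom.pattern == "patch":
        r = np.hypot(X - cx, Y - cy)
        disc = np.exp(-(r ** 2) / (2.0 * s * s))                       # proximal, down
        ann = np.exp(-((r - extent / 2.0) ** 2) / (2.0 * s * s))       # distal, up
        ann_sum, disc_sum = ann.sum(), disc.sum()
        if disc_sum > 0:
            disc *= ann_sum / disc_sum  # balance the axial load exactly
        f = ann - disc  # zero net axial load
        t[..., 2] = m * f / max(np.abs(f).max(), 1e-300)
    elif phantom.pattern == "rotational_moment":
        r = np.hypot(X - cx, Y - cy)
        band = np.exp(-((r - extent / 2.0) ** 2) / (2.0 * s * s))
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r > 0, -(Y - cy) / r, 0.0)
            uy = np.where(r > 0, (X - cx) / r, 0.0)
        t[..., 0] = m * band * ux
        t[..., 1] = m * band * uy
    return TractionField(t, pitch, metadata={"pattern": phantom.pattern})


def deform_phantom(
    vol: Volume,
    traction: TractionField,
    substrate: ElasticSubstrate,
    interpolation_order: int = 3,
) -> Volume:
    """Warp a relaxed bead volume by the elastic response to a traction field.

    The continuum displacement is evaluated at every z-plane depth through
    the elastic forward model (traction rendered on the volume's lateral
    grid), then the volume is warped by tricubic interpolation
    (``deformed(r) = relaxed(r - u(r))``), constant-padded with the
    background outside the domain.  The input is the relaxed (post-
    detachment) state; the output is the gel under traction.
    """
    nz, ny, nx = vol.shape
    dz, dy, dx = vol.pitch
    if traction.grid_shape != (ny, nx):
        raise ValueError("traction grid must be rendered on the volume lateral grid")
    depths = [iz * dz for iz in range(nz)]
    kernel = sample_greens_kernel((ny, nx), (dy, dx), depths, substrate)
    u = forward_displacement(traction, kernel)  # (nz, ny, nx, 3) um, z-up

    max_disp_vox = float(
        np.max(np.abs(u) / np.array([dx, dy, dz])[None, None, None, :])
    )
    if max_disp_vox > 32:
        import warnings

        warnings.warn(
            f"maximum displacement {max_disp_vox:.1f} voxels exceeds typical "
            "subset size; tracking will fail",
            RuntimeWarning,
            stacklevel=2,
        )

    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    # physical u -> index displacement: x,y follow array axes; z index grows
    # with depth, so an upward (positive uz) motion decreases the z index
    coords = np.stack(
        [
            zz + u[..., 2] / dz,   # sample deeper material that moved up
            yy - u[..., 1] / dy,
            xx - u[..., 0] / dx,
        ]
    )
    background = float(np.median(vol.data))
    warped = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float),
        coords,
        order=interpolation_order,
        mode="constant",
        cval=background,
    )
    return vol.copy(
        data=warped,
        deformed=True,
        traction_pattern=traction.metadata.get("pattern"),
        max_displacement_vox=max_disp_vox,
    )


def add_noise(vol: Volume, noise: NoiseSpec) -> Volume:
    """Add seeded Gaussian imaging noise; ``sigma = 0`` is the identity."""
    if noise.additive_sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(noise.seed)
    out = vol.data + rng.normal(0.0, noise.additive_sigma, size=vol.shape)
    return vol.copy(data=out, noise_sigma=noise.additive_sigma, noise_seed=noise.seed)
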