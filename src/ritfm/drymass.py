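"""Dry-mass quantification and per-cell traction metrics.

Refractive index is a linear proxy for non-aqueous (dry) mass: the RI excess
over the medium divided by the refraction increment ``alpha = dRI/dc =
0.185 mL/g`` gives the local protein concentration.  Integrating that
concentration axially yields a surface dry-mass density map (fg/um^2), whose
gravitational load (``g = 9.8 m/s^2``) is the "weight pressure" — a few
orders of magnitude below cell-generated tractions, which is the reason cell
weight can be neglected in traction force microscopy.

The remaining helpers compute the reported per-cell summaries: traction
histograms and statistics, frame-to-frame differential traction, kymographs,
and 3D morphology parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import TractionField
from .volume import Volume

__all__ = [
    "DryMassParams",
    "SurfaceDensityMap",
    "ri_to_density",
    "surface_density_map",
    "weight_pressure",
    "traction_stats",
    "differential_traction",
    "kymograph",
    "morphology_params",
]

# 1 g/mL integrated over 1 um of depth = 1000 fg/um^2
_GML_UM_TO_FG_UM2 = 1000.0
# 1 fg/um^2 = 1e-18 kg / 1e-12 m^2 = 1e-6 kg/m^2
_FG_UM2_TO_KG_M2 = 1e-6


@dataclass(frozen=True)
class DryMassParams:
    """Refraction-increment parameters.

    ``alpha_ri``: RI increment per protein concentration, mL/g (default
    0.185).  ``n_medium``: background (medium) refractive index — required,
    instrument-specific.  ``gravity``: m/s^2.
    """

    n_medium: float
    alpha_ri: float = 0.185
    gravity: float = 9.8

    def __post_init__(self) -> None:
        if self.alpha_ri <= 0:
            raise ValueError("alpha_ri must be positive")


@dataclass
class SurfaceDensityMap:
    """Projected dry-mass density on the lateral grid, fg/um^2 (>= 0)."""

    density: np.ndarray          # (ny, nx)
    pitch: tuple[float, float]   # (dy, dx) um
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 2:
            raise ValueError("surface density map must be 2D")


def ri_to_density(vol: Volume, params: DryMassParams) -> Volume:
    """Convert an RI volume to protein concentration ``c = (n - n_m)/alpha``.

    Output in g/mL.  Negative concentrations (noise below the medium RI) are
    clamped to zero and the clamped fraction recorded in metadata.
    """
    n = np.asarray(vol.data, dtype=float)
    if params.n_medium > n.max() + 1e-9:
        raise ValueError(
            f"n_medium {params.n_medium} exceeds the volume RI maximum "
            f"{n.max():.4f}; nothing to quantify"
        )
    c = (n - params.n_medium) / params.alpha_ri
    clamped = float((c < 0).mean())
    c = np.maximum(c, 0.0)
    return vol.copy(data=c, units="g/mL", fraction_clamped=clamped)


def total_dry_mass(density: Volume) -> float:
    """Total dry mass in picograms: sum of c * voxel volume (g/mL * um^3 = pg)."""
    return float(density.data.sum() * density.voxel_volume)


def surface_density_map(density: Volume, axis: int = 0) -> SurfaceDensityMap:
    """Axial integral of concentration per lateral pixel, in fg/um^2."""
    sigma = density.data.sum(axis=axis) * density.pitch[axis] * _GML_UM_TO_FG_UM2
    lateral_pitch = tuple(p for i, p in enumerate(density.pitch) if i != axis)
    return SurfaceDensityMap(
        np.maximum(sigma, 0.0), lateral_pitch, metadata={"units": "fg/um^2"}
    )


def weight_pressure(map_: SurfaceDensityMap, params: DryMassParams) -> np.ndarray:
    """Gravitational pressure of the dry mass, ``P = sigma g``, in pascal."""
    return map_.density * _FG_UM2_TO_KG_M2 * params.gravity


def traction_stats(traction: TractionField, threshold: float | None = None) -> dict:
    """Mean ± std and max of shear and normal traction, plus histograms.

    ``threshold`` (Pa) restricts the statistics to nodes whose total traction
    magnitude exceeds it (significant vectors only).  Histogram binning is
    Freedman–Diaconis.
    """
    shear = traction.shear_magnitude.ravel()
    normal = traction.normal.ravel()
    if shear.size == 0:
        raise ValueError("empty traction field")
    if threshold is not None:
        keep = np.linalg.norm(traction.t, axis=-1).ravel() > threshold
        if not keep.any():
            raise ValueError(f"no nodes above threshold {threshold} Pa")
        shear, normal = shear[keep], normal[keep]

    def _hist(v):
        if np.ptp(v) == 0:
            return np.histogram(v, bins=1)
        return np.histogram(v, bins="fd")

    return {
        "n": int(shear.size),
        "shear_mean": float(shear.mean()),
        "shear_std": float(shear.std()),
        "shear_max": float(shear.max()),
        "normal_mean": float(normal.mean()),
        "normal_std": float(normal.std()),
        "normal_max_up": float(normal.max()),
        "normal_max_down": float(normal.min()),
        "shear_hist": _hist(shear),
        "normal_hist": _hist(normal),
    }


def differential_traction(
    t_curr: TractionField, t_prev: TractionField | None
) -> TractionField:
    """Frame-to-frame traction change ``dT_j = T_j - T_{j-1}``.

    The first frame uses the zero-field convention (``T_0 = 0``), so
    ``dT_1 = T_1``.
    """
    if t_prev is None:
        return TractionField(
            t_curr.t.copy(), t_curr.pitch, t_curr.origin,
            metadata={"differential": True, "first_frame": True},
        )
    if t_prev.grid_shape != t_curr.grid_shape or t_prev.pitch != t_curr.pitch:
        raise ValueError("traction grids incongruent between frames")
    return TractionField(
        t_curr.t - t_prev.t, t_curr.pitch, t_curr.origin,
        metadata={"differential": True},
    )


def kymograph(maps, axis: str = "x", reduce: str = "max") -> np.ndarray:
    """Stack per-time 1D profiles of a series of 2D maps into (time, position).

    Each map is reduced across the other lateral axis by ``max`` or ``mean``;
    profiles run along ``axis`` (``x`` = array columns, ``y`` = rows).
    """
    maps = [np.asarray(m, dtype=float) for m in maps]
    if len(maps) < 2:
        raise ValueError("kymograph needs at least two timepoints")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps must be congruent across time")
    red = {"max": np.max, "mean": np.mean}.get(reduce)
    if red is None:
        raise ValueError(f"unknown reduction {reduce!r}")
    ax = {"x": 0, "y": 1}.get(axis)
    if ax is None:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    return np.stack([red(m, axis=ax) for m in maps])


def morphology_params(
    density: Volume,
    mask: np.ndarray | None = None,
    threshold: float = 0.02,
) -> dict:
    """Maximum cell thickness (um) and mean surface dry-mass density (fg/um^2).

    The cell support is either an explicit boolean mask or the voxels above
    the concentration ``threshold`` (g/mL).  Thickness is the axial extent of
    supra-threshold voxels per lateral pixel; the mean surface density runs
    over the lateral footprint of the support.
    """
    support = np.asarray(mask, dtype=bool) if mask is not None else (
        density.data > threshold
    )
    if support.shape != density.shape:
        raise ValueError("mask incongruent with volume")
    if not support.any():
        raise ValueError("empty cell support")
    thickness = support.sum(axis=0) * density.pitch[0]
    footprint = support.any(axis=0)
    smap = surface_density_map(density.copy(data=density.data * support))
    return {
        "max_thickness_um": float(thickness.max()),
        "mean_surface_density_fg_um2": float(smap.density[footprint].mean()),
        "footprint_px": int(footprint.sum()),
    }
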