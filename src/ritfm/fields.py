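"""Vector-field containers shared by tracking, the elastic model and the solver.

Conventions (package-wide):

* Lateral axes ``x``, ``y`` are the volume's last two array axes; ``z`` points
  **up**, from the gel into the cell.  The gel surface is the plane ``z = 0``
  and depth below the surface is reported as a positive ``depth`` coordinate.
* Displacements ``(ux, uy, uz)`` and tractions ``(Tx, Ty, Tz)`` use the same
  frame, so positive ``Tz`` means the cell pulls the gel surface upward.
* Displacement vectors live on a coarse 3D grid of tracking-window centres
  (units micrometres); tractions live on the 2D surface grid ``z = 0``
  (units pascal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DisplacementField", "TractionField"]


@dataclass
class DisplacementField:
    """Displacements on a coarse ``(nz, ny, nx)`` grid of window centres.

    Attributes
    ----------
    u
        ``(nz, ny, nx, 3)`` array of ``(ux, uy, uz)`` in micrometres.
    coords
        ``(nz, ny, nx, 3)`` array of node positions ``(x, y, depth)`` in
        micrometres; ``depth >= 0`` below the gel surface.
    valid
        Boolean mask of nodes whose vector was measured (not infilled).
    quality
        Per-node correlation peak quality in ``[0, 1]``.
    spacing
        Grid spacing ``(dz, dy, dx)`` in micrometres.
    """

    u: np.ndarray
    coords: np.ndarray
    valid: np.ndarray
    quality: np.ndarray
    spacing: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(f"u must have shape (nz, ny, nx, 3), got {self.u.shape}")
        if self.coords.shape != self.u.shape:
            raise ValueError("coords and u must have the same shape")
        if self.valid.shape != self.u.shape[:3]:
            raise ValueError("valid mask incongruent with grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def component(self, axis: str) -> np.ndarray:
        return self.u[..., "xyz".index(axis)]


@dataclass
class TractionField:
    """Surface traction vectors on the 2D grid ``z = 0``.

    ``t`` has shape ``(ny, nx, 3)`` holding ``(Tx, Ty, Tz)`` in pascal;
    ``pitch`` is the lateral node spacing ``(dy, dx)`` in micrometres.
    """

    t: np.ndarray
    pitch: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 3 or self.t.shape[-1] != 3:
            raise ValueError(f"t must have shape (ny, nx, 3), got {self.t.shape}")
        self.pitch = (float(self.pitch[0]), float(self.pitch[1]))
        if any(p <= 0 for p in self.pitch):
            raise ValueError("pitch must be positive")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.t.shape[:2]

    @property
    def cell_area_um2(self) -> float:
        return self.pitch[0] * self.pitch[1]

    @property
    def shear_magnitude(self) -> np.ndarray:
        """In-plane traction magnitude ``sqrt(Tx^2 + Ty^2)`` per node (Pa)."""
        return np.hypot(self.t[..., 0], self.t[..., 1])

    @property
    def normal(self) -> np.ndarray:
        """Out-of-plane component ``Tz`` (Pa), positive toward the cell."""
        return self.t[..., 2]

    def net_force(self) -> np.ndarray:
        """Net force vector (N): traction integrated over the surface grid."""
        area_m2 = self.cell_area_um2 * 1e-12
        return self.t.sum(axis=(0, 1)) * area_m2

    def gross_force(self) -> float:
        """Integral of |T| over the grid (N) — the scale for balance checks."""
        area_m2 = self.cell_area_um2 * 1e-12
        return float(np.linalg.norm(self.t, axis=-1).sum() * area_m2)
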