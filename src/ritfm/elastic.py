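"""Elastic half-space Green's tensor and the traction -> displacement operator.

The substrate is modelled as a linear, isotropic, semi-infinite elastic medium
(Young's modulus ``E``, Poisson ratio ``nu``, free surface at ``z = 0``).  A
point force applied at the surface produces the classical Boussinesq–Cerruti
displacement field; the 3x3 dyadic Green's tensor ``G`` collects the response
of each displacement component to each force component, with the familiar
prefactor ``(1 + nu) / (2 pi E)``.  For an incompressible gel (``nu = 0.5``)
the shear and normal problems decouple at the surface and the surface normal
response reduces to ``G_zz = 3 / (4 pi E rho)``.

Components follow the package frame: the third axis is positive **toward the
cell** (upward), while the ``z`` argument of :func:`greens_tensor` is the
depth of the field point below the surface (non-negative).  The sign map
between this frame and the classical depth-positive solution is applied once,
here.

The forward operator ``u = G (*) T`` is a per-component 2D convolution of the
surface traction with the sampled tensor, evaluated at one or more depth
planes; its exact adjoint is provided for gradient-based inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .fields import DisplacementField, TractionField

__all__ = [
    "ElasticSubstrate",
    "GreensKernel",
    "greens_tensor",
    "sample_greens_kernel",
    "forward_displacement",
    "adjoint_displacement",
]

# mean over a centred square cell of side a of 1/rho and x^2/rho^3:
#   <1/rho>      = 4 ln(1 + sqrt 2) / a
#   <x^2/rho^3>  = 2 ln(1 + sqrt 2) / a   (half of <1/rho> by x<->y symmetry)
_LN1P_SQRT2 = float(np.log(1.0 + np.sqrt(2.0)))


@dataclass(frozen=True)
class ElasticSubstrate:
    """Elastic gel parameters: Young's modulus ``E`` (Pa), Poisson ratio ``nu``.

    ``nu`` defaults to 0.5 (incompressible polyacrylamide).  The free surface
    is the plane ``z = 0`` with the gel below it.
    """

    E: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError(f"Poisson ratio must be in [0, 0.5], got {self.nu}")

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


def greens_tensor(x, y, z, substrate: ElasticSubstrate) -> np.ndarray:
    """Evaluate the half-space Green's tensor at field points (m/N).

    Parameters
    ----------
    x, y
        Lateral offsets from the point load, micrometres (broadcastable).
    z
        Depth of the field point below the surface, micrometres, ``z >= 0``.
    substrate
        Elastic parameters.

    Returns
    -------
    ndarray, shape ``broadcast(x, y, z).shape + (3, 3)``
        ``G[..., a, b]`` is displacement component ``a`` per unit point force
        along ``b``, in metres per newton.  The third component of force and
        displacement is positive upward (toward the cell).

    Raises
    ------
    ValueError
        If any field point sits at the singular origin or below the surface
        (``z < 0``).
    """
    x = np.asarray(x, dtype=float) * 1e-6  # um -> m
    y = np.asarray(y, dtype=float) * 1e-6
    z = np.asarray(z, dtype=float) * 1e-6
    x, y, z = np.broadcast_arrays(x, y, z)
    if np.any(z < 0):
        raise ValueError("field points must lie in the gel (depth z >= 0)")
    rho2 = x * x + y * y
    r = np.sqrt(rho2 + z * z)
    if np.any(r == 0):
        raise ValueError(
            "Green's tensor is singular at the load point; use "
            "sample_greens_kernel for a regularized origin cell"
        )
    nu = substrate.nu
    C = (1.0 + nu) / (2.0 * np.pi * substrate.E)
    k = 1.0 - 2.0 * nu
    rz = r + z
    r3 = r ** 3

    G = np.empty(r.shape + (3, 3), dtype=float)
    G[..., 0, 0] = 1.0 / r + x * x / r3 + k * (1.0 / rz - x * x / (r * rz * rz))
    G[..., 1, 1] = 1.0 / r + y * y / r3 + k * (1.0 / rz - y * y / (r * rz * rz))
    G[..., 2, 2] = z * z / r3 + 2.0 * (1.0 - nu) / r
    G[..., 0, 1] = G[..., 1, 0] = x * y / r3 - k * x * y / (r * rz * rz)
    # coupling terms in the depth-positive (classical) frame, then sign-mapped
    # to the z-up reporting frame: S G S with S = diag(1, 1, -1)
    G[..., 0, 2] = -(x * z / r3 - k * x / (r * rz))
    G[..., 1, 2] = -(y * z / r3 - k * y / (r * rz))
    G[..., 2, 0] = -(x * z / r3 + k * x / (r * rz))
    G[..., 2, 1] = -(y * z / r3 + k * y / (r * rz))
    return G * C


def _origin_cell_average(pitch_um: float, substrate: ElasticSubstrate) -> np.ndarray:
    """Analytic average of G over the square surface cell containing the load.

    At ``z = 0`` the diagonal terms reduce to ``(2 - 2 nu)/rho + 2 nu x^2/rho^3``
    (lateral) and ``2 (1 - nu)/rho`` (normal); the odd off-diagonal terms
    average to zero over the symmetric cell.
    """
    a = pitch_um * 1e-6
    nu = substrate.nu
    C = (1.0 + nu) / (2.0 * np.pi * substrate.E)
    m_inv_rho = 4.0 * _LN1P_SQRT2 / a          # <1/rho>
    m_x2_rho3 = 2.0 * _LN1P_SQRT2 / a          # <x^2/rho^3>
    G = np.zeros((3, 3))
    G[0, 0] = G[1, 1] = C * ((2.0 - 2.0 * nu) * m_inv_rho + 2.0 * nu * m_x2_rho3)
    G[2, 2] = C * 2.0 * (1.0 - nu) * m_inv_rho
    return G


@dataclass
class GreensKernel:
    """Green's tensor sampled on a lateral offset grid at a set of depths.

    ``values`` has shape ``(n_depths, 3, 3, 2*ny - 1, 2*nx - 1)`` (m/N),
    indexed so that the zero lateral offset sits at the centre.  The singular
    surface cell is replaced by its analytic cell average (or a quarter-cell
    offset evaluation for non-square cells), recorded in ``origin_treatment``.
    """

    values: np.ndarray
    pitch: tuple[float, float]           # (dy, dx) um
    depths: tuple[float, ...]            # um, >= 0
    substrate: ElasticSubstrate
    grid_shape: tuple[int, int]          # (ny, nx) of the traction grid
    origin_treatment: str = "analytic-cell-average"
    trunc_radius: int | None = None
    metadata: dict = field(default_factory=dict)


def sample_greens_kernel(
    grid_shape: tuple[int, int],
    pitch: tuple[float, float],
    depths,
    substrate: ElasticSubstrate,
    trunc_radius: int | None = None,
) -> GreensKernel:
    """Sample the tensor at every lateral grid offset and each depth plane.

    Parameters
    ----------
    grid_shape
        ``(ny, nx)`` of the traction grid; offsets span ``±(n - 1)`` nodes so
        the convolution is exact (no wraparound).
    pitch
        Lateral node spacing ``(dy, dx)`` in micrometres.
    depths
        Depth planes (micrometres, ``>= 0``) at which displacement is needed;
        typically the two displacement-grid planes nearest the surface.
    trunc_radius
        If given, zero the kernel beyond this many nodes of lateral offset —
        each displacement vector is then fitted only from its local
        neighbourhood (a ``(2R) x (2R)`` stencil per depth).
    """
    depths = tuple(float(d) for d in depths)
    if len(depths) == 0:
        raise ValueError("at least one depth plane is required")
    if any(d < 0 for d in depths):
        raise ValueError("depths must be non-negative")
    ny, nx = grid_shape
    dy, dx = float(pitch[0]), float(pitch[1])
    if dy <= 0 or dx <= 0:
        raise ValueError("pitch must be positive")
    oy = np.arange(-(ny - 1), ny) * dy
    ox = np.arange(-(nx - 1), nx) * dx
    X = ox[None, :] * np.ones((oy.size, 1))
    Y = oy[:, None] * np.ones((1, ox.size))

    vals = np.empty((len(depths), 3, 3, oy.size, ox.size))
    origin_treatment = "none"
    for d_i, d in enumerate(depths):
        Z = np.full_like(X, d)
        singular = (X == 0) & (Y == 0) & (Z == 0)
        if singular.any():
            Xs = X.copy()
            Xs[singular] = dx  # placeholder, overwritten below
            G = greens_tensor(Xs, Y, Z, substrate)
            iy, ix = np.argwhere(singular)[0]
            if abs(dx - dy) <= 1e-9 * max(dx, dy):
                G[iy, ix] = _origin_cell_average(dx, substrate)
                origin_treatment = "analytic-cell-average"
            else:
                G[iy, ix] = greens_tensor(dx / 4.0, dy / 4.0, 0.0, substrate)
                origin_treatment = "quarter-cell-offset"
        else:
            G = greens_tensor(X, Y, Z, substrate)
        vals[d_i] = np.moveaxis(G, (-2, -1), (0, 1))

    if trunc_radius is not None:
        keep = (np.abs(oy[:, None]) <= trunc_radius * dy + 1e-9) & (
            np.abs(ox[None, :]) <= trunc_radius * dx + 1e-9
        )
        vals *= keep[None, None, None]

    return GreensKernel(
        values=vals,
        pitch=(dy, dx),
        depths=depths,
        substrate=substrate,
        grid_shape=(ny, nx),
        origin_treatment=origin_treatment,
        trunc_radius=trunc_radius,
    )


def _check_grid(t_shape: tuple[int, int], kernel: GreensKernel) -> None:
    if tuple(t_shape) != tuple(kernel.grid_shape):
        raise ValueError(
            f"grid mismatch: field grid {t_shape} vs kernel grid {kernel.grid_shape}"
        )


def forward_displacement(traction: TractionField, kernel: GreensKernel) -> np.ndarray:
    """Displacement (micrometres) generated by a surface traction field.

    Returns an array of shape ``(n_depths, ny, nx, 3)``: the continuum
    displacement at each traction-grid node and each kernel depth plane.  The
    convolution is an exact linear convolution (full-size kernel, FFT
    evaluated), identical to the direct double sum to rounding error.
    """
    _check_grid(traction.grid_shape, kernel)
    t = traction.t
    ny, nx = t.shape[:2]
    area_m2 = kernel.pitch[0] * kernel.pitch[1] * 1e-12
    out = np.zeros((len(kernel.depths), ny, nx, 3))
    for d in range(len(kernel.depths)):
        for a in range(3):
            acc = np.zeros((ny, nx))
            for b in range(3):
                if not np.any(t[..., b]):
                    continue
                acc += fftconvolve(t[..., b], kernel.values[d, a, b], mode="same")
            out[d, ..., a] = acc
    # G [m/N] * T [Pa] * dA [m^2] -> metres; report micrometres
    return out * area_m2 * 1e6


def adjoint_displacement(u: np.ndarray, kernel: GreensKernel) -> np.ndarray:
    """Exact adjoint of :func:`forward_displacement`.

    Maps a displacement-space array ``(n_depths, ny, nx, 3)`` (micrometres)
    back to traction space ``(ny, nx, 3)``; satisfies
    ``<forward(T), u> = <T, adjoint(u)>`` to rounding error.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[0] != len(kernel.depths) or u.shape[-1] != 3:
        raise ValueError("displacement array incongruent with kernel")
    _check_grid(u.shape[1:3], kernel)
    ny, nx = u.shape[1:3]
    area_m2 = kernel.pitch[0] * kernel.pitch[1] * 1e-12
    out = np.zeros((ny, nx, 3))
    for b in range(3):
        acc = np.zeros((ny, nx))
        for d in range(len(kernel.depths)):
            for a in range(3):
                # adjoint of conv with K is correlation: conv with flipped K
                flipped = kernel.values[d, a, b][::-1, ::-1]
                acc += fftconvolve(u[d, ..., a], flipped, mode="same")
        out[..., b] = acc
    return out * area_m2 * 1e6
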