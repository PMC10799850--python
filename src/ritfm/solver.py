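"""Monotone constrained-TV FISTA engine and the traction inverse problem.

Both inverse problems in this package share one objective,

    argmin_x  1/2 || y - A x ||_2^2  +  tau || grad x ||_1 ,

where ``A`` is a linear forward operator (the elastic Green's convolution for
traction reconstruction; a point-spread-function convolution for volume
deconvolution) and the regularizer is isotropic total variation applied to
each vector component independently.  The solver is the monotone variant of
accelerated proximal gradient descent (MFISTA): each outer iteration takes a
gradient step, applies the TV proximal map by dual fast gradient projection
(the "inner" iterations), and keeps the better of the candidate and the
previous iterate, so the objective trace is non-increasing by construction.

Every solve is deterministic: zero (or explicitly given) initialization and
no randomness.  Inverse problems are non-dimensionalized internally — the
operator is scaled to unit spectral norm and the data to unit L2 norm — so
that the step size ``alpha`` and TV weight ``tau`` in :class:`FISTAConfig`
are scale-free and portable across problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .elastic import (
    ElasticSubstrate,
    GreensKernel,
    adjoint_displacement,
    forward_displacement,
    sample_greens_kernel,
)
from .fields import DisplacementField, TractionField
from .volume import Volume

__all__ = [
    "FISTAConfig",
    "SolveReport",
    "tv_prox",
    "fista_solve",
    "reconstruct_traction",
    "deconvolve_volume",
    "DECONV_STAGE1",
    "DECONV_STAGE2",
]


@dataclass(frozen=True)
class FISTAConfig:
    """Parameters of the monotone TV-FISTA solve.

    Defaults are the traction-reconstruction settings (step size 0.01, TV
    weight 0.02, 200 inner / 240 outer iterations, monotone).  ``step_size``
    is the gradient step for the unit-spectral-norm operator; the solver
    warns if it exceeds the inverse Lipschitz bound ``1/L``.
    """

    step_size: float = 0.01
    tv_weight: float = 0.02
    inner_iterations: int = 200
    outer_iterations: int = 240
    monotone: bool = True
    nonnegativity: bool = False

    def __post_init__(self) -> None:
        if not self.step_size > 0:
            raise ValueError("step_size must be positive")
        if self.tv_weight < 0:
            raise ValueError("tv_weight must be non-negative")
        if self.inner_iterations < 1 or self.outer_iterations < 1:
            raise ValueError("iteration counts must be >= 1")


# two-stage multiscale schedule for RI volume deconvolution
DECONV_STAGE1 = FISTAConfig(step_size=0.003, tv_weight=0.003,
                            inner_iterations=100, outer_iterations=75)
DECONV_STAGE2 = FISTAConfig(step_size=0.006, tv_weight=0.006,
                            inner_iterations=50, outer_iterations=25)


@dataclass
class SolveReport:
    """Objective trace and diagnostics of one TV-FISTA solve."""

    objective: np.ndarray          # total objective per accepted outer iterate
    data_fidelity: np.ndarray
    tv_term: np.ndarray
    monotone: bool
    converged: bool
    restarts: int = 0
    lipschitz: float | None = None
    scales: dict = field(default_factory=dict)

    @property
    def n_outer(self) -> int:
        return len(self.objective)


def _forward_diff(x: np.ndarray, axes) -> list[np.ndarray]:
    grads = []
    for ax in axes:
        g = np.zeros_like(x)
        sl_hi = [slice(None)] * x.ndim
        sl_lo = [slice(None)] * x.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        g[tuple(sl_lo)] = x[tuple(sl_hi)] - x[tuple(sl_lo)]
        grads.append(g)
    return grads


def _divergence(p: list[np.ndarray], axes) -> np.ndarray:
    # negative adjoint of _forward_diff
    div = np.zeros_like(p[0])
    for g, ax in zip(p, axes):
        d = np.zeros_like(g)
        sl_hi = [slice(None)] * g.ndim
        sl_lo = [slice(None)] * g.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        d[tuple(sl_hi)] = g[tuple(sl_lo)]
        div += g - d
    return div


def total_variation(x: np.ndarray, axes=None, isotropic: bool = True) -> float:
    """Discrete TV of ``x`` over the given spatial axes (forward differences)."""
    axes = tuple(range(x.ndim)) if axes is None else tuple(axes)
    grads = _forward_diff(np.asarray(x, dtype=float), axes)
    if isotropic:
        return float(np.sqrt(sum(g * g for g in grads)).sum())
    return float(sum(np.abs(g).sum() for g in grads))


def tv_prox(
    x: np.ndarray,
    weight: float,
    inner_iterations: int = 50,
    axes=None,
    isotropic: bool = True,
    nonnegativity: bool = False,
) -> np.ndarray:
    """Proximal map of ``weight * TV`` by dual fast gradient projection.

    Solves ``argmin_u 1/2 ||u - x||^2 + weight * TV(u)`` (optionally subject
    to ``u >= 0``) with ``inner_iterations`` accelerated dual steps.  A zero
    weight returns the input unchanged (after the optional projection).
    """
    x = np.asarray(x, dtype=float)
    if weight < 0:
        raise ValueError("weight must be non-negative")
    project = (lambda v: np.maximum(v, 0.0)) if nonnegativity else (lambda v: v)
    if weight == 0:
        return project(x.copy())
    axes = tuple(range(x.ndim)) if axes is None else tuple(axes)
    L = 4.0 * len(axes)  # Lipschitz bound of the dual gradient
    p = [np.zeros_like(x) for _ in axes]
    r = [q.copy() for q in p]
    t = 1.0
    for _ in range(inner_iterations):
        u = project(x + weight * _divergence(r, axes))
        g = _forward_diff(u, axes)
        q = [rk + (1.0 / (weight * L)) * gk for rk, gk in zip(r, g)]
        if isotropic:
            mag = np.sqrt(sum(qk * qk for qk in q))
            denom = np.maximum(mag, 1.0)
            q = [qk / denom for qk in q]
        else:
            q = [np.clip(qk, -1.0, 1.0) for qk in q]
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        r = [qk + ((t - 1.0) / t_next) * (qk - pk) for qk, pk in zip(q, p)]
        p, t = q, t_next
    return project(x + weight * _divergence(p, axes))


def estimate_operator_norm(op, adjoint, shape, n_iter: int = 30) -> float:
    """Spectral norm ``||A||`` by power iteration on ``A^T A`` (deterministic)."""
    rng = np.random.default_rng(0)
    v = rng.standard_normal(shape)
    v /= np.linalg.norm(v)
    s = 0.0
    for _ in range(n_iter):
        w = adjoint(op(v))
        n = np.linalg.norm(w)
        if n == 0:
            return 0.0
        s = n
        v = w / n
    return float(np.sqrt(s))


def fista_solve(
    operator,
    adjoint,
    data: np.ndarray,
    cfg: FISTAConfig,
    x_shape=None,
    x0: np.ndarray | None = None,
    tv_axes=None,
    check_adjoint: bool = True,
    operator_norm: float | None = None,
):
    """Minimize ``1/2 ||data - A x||^2 + tau TV(x)`` with monotone FISTA.

    Parameters
    ----------
    operator, adjoint
        Callables implementing ``A`` and ``A^T`` on ndarrays.
    data
        Observed array ``y``.
    cfg
        Solver parameters; ``cfg.step_size`` is checked against the power-
        iteration Lipschitz bound and a warning is issued if it exceeds 1/L.
    x_shape
        Shape of the unknown (defaults to ``data.shape``).
    x0
        Starting iterate (defaults to zeros — deterministic).
    tv_axes
        Axes over which TV is taken (defaults to all axes of ``x``).

    Returns
    -------
    (x, SolveReport)
    """
    data = np.asarray(data, dtype=float)
    shape = tuple(x_shape) if x_shape is not None else data.shape
    x = np.zeros(shape) if x0 is None else np.asarray(x0, dtype=float).copy()

    if check_adjoint:
        rng = np.random.default_rng(1)
        tx = rng.standard_normal(shape)
        ty = rng.standard_normal(data.shape)
        lhs = np.vdot(operator(tx), ty)
        rhs = np.vdot(tx, adjoint(ty))
        denom = max(abs(lhs), abs(rhs), 1e-300)
        if abs(lhs - rhs) / denom > 1e-8:
            raise ValueError("operator/adjoint pair fails the dot-product test")

    if operator_norm is None:
        operator_norm = estimate_operator_norm(operator, adjoint, shape)
    L = operator_norm ** 2
    if L > 0 and cfg.step_size > 1.0 / L * (1.0 + 1e-9):
        warnings.warn(
            f"step size {cfg.step_size} exceeds 1/L = {1.0 / L:.3g}; "
            "FISTA may diverge",
            RuntimeWarning,
            stacklevel=2,
        )

    axes = tuple(range(x.ndim)) if tv_axes is None else tuple(tv_axes)
    alpha, tau = cfg.step_size, cfg.tv_weight

    def objective(v):
        resid = operator(v) - data
        fid = 0.5 * float(np.vdot(resid, resid).real)
        tv = tau * total_variation(v, axes) if tau > 0 else 0.0
        return fid, tv

    fid, tv = objective(x)
    f_x = fid + tv
    y = x.copy()
    t = 1.0
    obj_trace, fid_trace, tv_trace = [f_x], [fid], [tv]
    restarts = 0

    for _ in range(cfg.outer_iterations):
        grad = adjoint(operator(y) - data)
        z = tv_prox(
            y - alpha * grad,
            alpha * tau,
            inner_iterations=cfg.inner_iterations,
            axes=axes,
            nonnegativity=cfg.nonnegativity,
        )
        if not np.all(np.isfinite(z)):
            raise RuntimeError(
                "NaN/Inf in FISTA iterate — step size too large for this operator"
            )
        fid_z, tv_z = objective(z)
        f_z = fid_z + tv_z
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        x_prev = x
        if cfg.monotone and f_z > f_x:
            # candidate rejected: keep the previous iterate (monotone trace)
            restarts += 1
            fid_new, tv_new = fid_trace[-1], tv_trace[-1]
        else:
            x, f_x = z, f_z
            fid_new, tv_new = fid_z, tv_z
        # monotone-FISTA momentum (reduces to plain FISTA when x == z)
        y = x + (t / t_next) * (z - x) + ((t - 1.0) / t_next) * (x - x_prev)
        obj_trace.append(f_x)
        fid_trace.append(fid_new)
        tv_trace.append(tv_new)
        t = t_next

    report = SolveReport(
        objective=np.asarray(obj_trace),
        data_fidelity=np.asarray(fid_trace),
        tv_term=np.asarray(tv_trace),
        monotone=cfg.monotone,
        converged=bool(
            len(obj_trace) > 1
            and abs(obj_trace[-1] - obj_trace[-2])
            <= 1e-8 * max(obj_trace[0], 1e-300)
        ),
        restarts=restarts,
        lipschitz=L,
    )
    return x, report


def _surface_planes(field: DisplacementField, n_planes: int = 2):
    """Indices and depths of the displacement planes nearest the gel surface."""
    depths = field.coords[:, 0, 0, 2]
    order = np.argsort(depths)[: max(1, min(n_planes, depths.size))]
    order = np.sort(order)
    return order, tuple(float(depths[i]) for i in order)


def reconstruct_traction(
    field: DisplacementField,
    substrate: ElasticSubstrate,
    cfg: FISTAConfig | None = None,
    n_depth_planes: int = 2,
    trunc_radius: int | None = None,
    surface_only: bool = False,
    kernel: GreensKernel | None = None,
):
    """Invert a displacement field into surface traction (Pa).

    The displacement vectors on the ``n_depth_planes`` grid planes nearest
    the surface (default two, i.e. each traction vector is constrained by a
    local ``2 R x 2 R x 2`` block of neighbouring displacement vectors, with
    ``R = trunc_radius`` nodes of Green's-kernel support) are fitted by a
    single global monotone TV-FISTA solve of the elastic inverse problem.

    Parameters
    ----------
    field
        Complete displacement field (invalid nodes already infilled).
    substrate
        Gel elastic parameters.
    cfg
        Solver settings; defaults to the traction defaults of
        :class:`FISTAConfig`.
    trunc_radius
        Lateral truncation of the Green's kernel in grid nodes
        (``None`` keeps the full long-range kernel).
    surface_only
        Evaluate the kernel at ``z = 0`` for all displacement planes instead
        of at each plane's depth.

    Returns
    -------
    (TractionField, SolveReport)
    """
    cfg = cfg or FISTAConfig()
    if not np.all(np.isfinite(field.u)):
        raise ValueError("displacement field contains non-finite vectors; infill first")
    plane_idx, depths = _surface_planes(field, n_depth_planes)
    if surface_only:
        depths = tuple(0.0 for _ in depths)
    nz, ny, nx = field.grid_shape
    dy, dx = field.spacing[1], field.spacing[2]
    if kernel is None:
        kernel = sample_greens_kernel(
            (ny, nx), (dy, dx), depths, substrate, trunc_radius=trunc_radius
        )
    elif tuple(kernel.grid_shape) != (ny, nx):
        raise ValueError("supplied kernel does not match the displacement grid")

    u_data = field.u[plane_idx]  # (n_planes, ny, nx, 3), um

    if not np.any(u_data):
        t = TractionField(np.zeros((ny, nx, 3)), (dy, dx))
        report = SolveReport(
            objective=np.zeros(1), data_fidelity=np.zeros(1), tv_term=np.zeros(1),
            monotone=cfg.monotone, converged=True, lipschitz=0.0,
        )
        return t, report

    def op_raw(tarr):
        return forward_displacement(TractionField(tarr, (dy, dx)), kernel)

    def adj_raw(uarr):
        return adjoint_displacement(uarr, kernel)

    s_A = estimate_operator_norm(op_raw, adj_raw, (ny, nx, 3))
    s_u = float(np.sqrt(np.mean(u_data ** 2)))  # per-node RMS scale
    # dimensionless problem: u~ = u / s_u,  x = T s_A / s_u,  A~ = A / s_A
    op = lambda x: op_raw(x) / s_A
    adj = lambda u_: adj_raw(u_) / s_A

    x, report = fista_solve(
        op,
        adj,
        u_data / s_u,
        cfg,
        x_shape=(ny, nx, 3),
        tv_axes=(0, 1),
        check_adjoint=False,
        operator_norm=1.0,
    )
    report.scales = {"operator_norm": s_A, "data_norm": s_u}
    traction = TractionField(
        x * (s_u / s_A),
        (dy, dx),
        metadata={
            "E_Pa": substrate.E,
            "nu": substrate.nu,
            "depths_um": depths,
            "trunc_radius": trunc_radius,
            "solver": "monotone TV-FISTA",
        },
    )
    return traction, report


def local_patch_traction(
    field: DisplacementField,
    substrate: ElasticSubstrate,
    patch: tuple[int, int, int] = (10, 10, 2),
) -> TractionField:
    """Per-node local least-squares traction (cross-check mode, unregularized).

    Each traction vector is fitted independently from the ``px x py x pz``
    block of neighbouring displacement vectors around its node, treating all
    other tractions as zero.  This is a deliberately crude, regularization-
    free estimator used to cross-check the global TV solve; it underestimates
    extended traction patches because it ignores neighbour contributions.
    """
    plane_idx, depths = _surface_planes(field, patch[2])
    ny, nx = field.grid_shape[1:]
    dy, dx = field.spacing[1], field.spacing[2]
    kernel = sample_greens_kernel((ny, nx), (dy, dx), depths, substrate)
    u = field.u[plane_idx]
    area_m2 = dy * dx * 1e-12
    hy, hx = patch[0] // 2, patch[1] // 2
    cy, cx = ny - 1, nx - 1  # kernel centre
    t = np.zeros((ny, nx, 3))
    for iy in range(ny):
        for ix in range(nx):
            rows = []
            rhs = []
            for d in range(len(depths)):
                for jy in range(max(0, iy - hy), min(ny, iy + hy + 1)):
                    for jx in range(max(0, ix - hx), min(nx, ix + hx + 1)):
                        # displacement at (jy, jx) from a unit traction at (iy, ix)
                        g = kernel.values[d, :, :, cy + (jy - iy), cx + (jx - ix)]
                        rows.append(g * area_m2 * 1e6)
                        rhs.append(u[d, jy, jx])
            A = np.concatenate(rows, axis=0).reshape(-1, 3)
            b = np.concatenate(rhs)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            t[iy, ix] = sol
    return TractionField(t, (dy, dx), metadata={"solver": "local-patch-lstsq"})


def _psf_conv_ops(psf: np.ndarray):
    flipped = psf[::-1, ::-1, ::-1]
    op = lambda x: fftconvolve(x, psf, mode="same")
    adj = lambda y: fftconvolve(y, flipped, mode="same")
    return op, adj


def deconvolve_volume(
    vol: Volume,
    psf: Volume,
    stages: tuple[FISTAConfig, FISTAConfig] = (DECONV_STAGE1, DECONV_STAGE2),
    downsample: int = 3,
    nonnegativity: bool = True,
) -> tuple[Volume, list[SolveReport]]:
    """Two-stage multiscale TV deconvolution of an RI volume.

    The volume is first down-sampled by ``downsample`` and deconvolved with
    the coarse-stage settings, then up-sampled to the original size and
    deconvolved again with the fine-stage settings.  The optional
    non-negativity constraint applies to the RI contrast.  Each stage warm
    starts from its observed/up-sampled image, so the result is a strict,
    deterministic refinement.
    """
    psf_arr = np.asarray(psf.data, dtype=float)
    if any(ps > vs for ps, vs in zip(psf_arr.shape, vol.data.shape)):
        raise ValueError("PSF larger than the volume")
    s = psf_arr.sum()
    if not np.isclose(s, 1.0, rtol=1e-6):
        raise ValueError("PSF must be normalized to unit sum")
    data = np.asarray(vol.data, dtype=float)
    # dimensionless frame: PSF convolution has unit DC gain, data scaled to
    # unit per-voxel RMS so the stage step sizes and TV weights are portable
    s_y = float(np.sqrt(np.mean(data ** 2))) or 1.0
    data = data / s_y
    reports: list[SolveReport] = []

    # stage 1: coarse scale
    zoom_dn = 1.0 / downsample
    coarse = ndimage.zoom(data, zoom_dn, order=1)
    psf_c = ndimage.zoom(psf_arr, zoom_dn, order=1)
    psf_c = psf_c / psf_c.sum() if psf_c.sum() > 0 else psf_c
    cfg1 = replace(stages[0], nonnegativity=nonnegativity)
    op, adj = _psf_conv_ops(psf_c)
    x1, rep1 = fista_solve(op, adj, coarse, cfg1, x0=coarse, check_adjoint=False)
    reports.append(rep1)

    # stage 2: full scale, warm started from the up-sampled coarse estimate
    up = ndimage.zoom(x1, np.array(data.shape) / np.array(x1.shape), order=3)
    if nonnegativity:
        up = np.maximum(up, 0.0)
    cfg2 = replace(stages[1], nonnegativity=nonnegativity)
    op, adj = _psf_conv_ops(psf_arr)
    x2, rep2 = fista_solve(op, adj, data, cfg2, x0=up, check_adjoint=False)
    reports.append(rep2)

    return vol.copy(data=x2 * s_y, deconvolved=True), reports
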