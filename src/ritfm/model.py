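"""Model/results interface for traction reconstruction.

:class:`TractionModel` is built from data — a measured displacement field
(or a raw volume pair) plus the substrate's elastic parameters — and
``fit()`` returns a :class:`TractionResults` carrying the estimated traction
field, solver diagnostics, and a ``summary()`` table of the per-cell traction
statistics.  Simulation (``simulate()``) pushes a traction field through the
forward elastic model, closing the loop for validation.
"""

from __future__ import annotations

import numpy as np

from .drymass import traction_stats
from .elastic import ElasticSubstrate, forward_displacement, sample_greens_kernel
from .fields import DisplacementField, TractionField
from .solver import FISTAConfig, SolveReport, reconstruct_traction
from .tracking import TrackingConfig, estimate_displacement_field
from .volume import Volume

__all__ = ["TractionModel", "TractionResults"]


class TractionModel:
    """Elastic inverse model: surface traction from substrate displacement.

    Parameters
    ----------
    displacement
        Measured displacement field (complete grid).
    substrate
        Gel elastic parameters (``E`` in Pa, ``nu``).
    fista
        Solver configuration; defaults to the standard traction settings.
    n_depth_planes, trunc_radius, surface_only
        Forward-operator options (see
        :func:`ritfm.solver.reconstruct_traction`).
    """

    def __init__(
        self,
        displacement: DisplacementField,
        substrate: ElasticSubstrate,
        fista: FISTAConfig | None = None,
        n_depth_planes: int = 2,
        trunc_radius: int | None = None,
        surface_only: bool = False,
    ):
        self.displacement = displacement
        self.substrate = substrate
        self.fista = fista or FISTAConfig()
        self.n_depth_planes = n_depth_planes
        self.trunc_radius = trunc_radius
        self.surface_only = surface_only

    @classmethod
    def from_volumes(
        cls,
        ref: Volume,
        mov: Volume,
        substrate: ElasticSubstrate,
        tracking: TrackingConfig | None = None,
        mask=None,
        **kwargs,
    ) -> "TractionModel":
        """Track a reference/deformed volume pair, then build the model."""
        field = estimate_displacement_field(ref, mov, tracking, mask)
        return cls(field, substrate, **kwargs)

    def fit(self) -> "TractionResults":
        """Run the monotone TV-FISTA inversion and wrap the results."""
        traction, report = reconstruct_traction(
            self.displacement,
            self.substrate,
            self.fista,
            n_depth_planes=self.n_depth_planes,
            trunc_radius=self.trunc_radius,
            surface_only=self.surface_only,
        )
        return TractionResults(self, traction, report)

    def simulate(
        self, traction: TractionField, depths=None
    ) -> np.ndarray:
        """Forward-model displacement (um) for a given traction field."""
        nz, ny, nx = self.displacement.grid_shape
        if depths is None:
            d = np.unique(self.displacement.coords[..., 2])
            depths = tuple(np.sort(d)[: self.n_depth_planes])
        kernel = sample_greens_kernel(
            (ny, nx),
            (self.displacement.spacing[1], self.displacement.spacing[2]),
            depths,
            self.substrate,
        )
        return forward_displacement(traction, kernel)


class TractionResults:
    """Fitted traction field with diagnostics.

    Attributes
    ----------
    traction : TractionField
        Estimated surface traction (Pa).
    report : SolveReport
        Objective trace, restart count, operator norm.
    """

    def __init__(self, model: TractionModel, traction: TractionField,
                 report: SolveReport):
        self.model = model
        self.traction = traction
        self.report = report

    @property
    def converged(self) -> bool:
        return self.report.converged

    @property
    def objective_trace(self) -> np.ndarray:
        return self.report.objective

    def residual_rms_um(self) -> float:
        """RMS misfit between measured and model-predicted displacement."""
        pred = self.model.simulate(self.traction)
        idx = np.argsort(self.model.displacement.coords[:, 0, 0, 2])
        meas = self.model.displacement.u[idx[: pred.shape[0]]]
        return float(np.sqrt(np.mean((pred - meas) ** 2)))

    def stats(self, threshold: float | None = None) -> dict:
        return traction_stats(self.traction, threshold)

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        s = self.stats()
        net = self.traction.net_force()
        gross = self.traction.gross_force()
        rep = self.report
        lines = [
            "          Traction reconstruction (monotone TV-FISTA)",
            "=" * 64,
            f"Substrate E: {self.model.substrate.E:.6g} Pa"
            f"    nu: {self.model.substrate.nu:.3g}",
            f"Grid: {self.traction.grid_shape[0]} x {self.traction.grid_shape[1]}"
            f" nodes at {self.traction.pitch[1]:.3g} um",
            f"Depth planes (um): "
            f"{tuple(round(d, 3) for d in self.traction.metadata.get('depths_um', ()))}",
            f"Outer iterations: {rep.n_outer - 1}"
            f"    restarts: {rep.restarts}    monotone: {rep.monotone}",
            f"Objective: {rep.objective[0]:.6g} -> {rep.objective[-1]:.6g}",
            "-" * 64,
            f"Shear  |T_xy| (Pa): mean {s['shear_mean']:.4g}"
            f" +/- {s['shear_std']:.4g}   max {s['shear_max']:.4g}",
            f"Normal  T_z  (Pa): mean {s['normal_mean']:.4g}"
            f" +/- {s['normal_std']:.4g}   max up {s['normal_max_up']:.4g}"
            f"   max down {s['normal_max_down']:.4g}",
            f"Net force (nN): ({net[0] * 1e9:.3g}, {net[1] * 1e9:.3g},"
            f" {net[2] * 1e9:.3g})   |net|/gross:"
            f" {np.linalg.norm(net) / gross if gross > 0 else 0.0:.3g}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot(self, ax=None, quiver_step: int = 1):
        """Shear quiver over a normal-traction map (matplotlib axes)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        t = self.traction
        ny, nx = t.grid_shape
        extent = (0, nx * t.pitch[1], 0, ny * t.pitch[0])
        im = ax.imshow(t.normal, origin="lower", extent=extent, cmap="RdBu_r")
        plt.colorbar(im, ax=ax, label="normal traction $T_z$ (Pa)")
        ys = np.arange(0, ny, quiver_step) * t.pitch[0]
        xs = np.arange(0, nx, quiver_step) * t.pitch[1]
        X, Y = np.meshgrid(xs, ys)
        ax.quiver(
            X, Y,
            t.t[::quiver_step, ::quiver_step, 0],
            t.t[::quiver_step, ::quiver_step, 1],
            color="k", scale_units="xy",
        )
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.set_title("shear (arrows) and normal (colour) traction")
        return ax
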