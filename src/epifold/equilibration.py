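"""Quasistatic relaxation and incremental tension-ramp protocols.

The model describes equilibrium tissue shapes: a ramp incrementally rescales
the tension parameters of the pre-fold stripe and re-relaxes the tissue to
mechanical equilibrium at every step, warm-starting from the previous
equilibrium.  The ramp magnitude serves as the analog of the time axis; the
dynamics of folding itself is out of scope.

Relaxation is a deterministic quasi-Newton (L-BFGS) descent on all vertex
coordinates with an exact analytic gradient; runs are reproducible given the
configuration.  Box dimensions are held fixed during ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, root

from .geometry import PRE_FOLD, TissueMesh
from .mechanics import MechanicalParams, energy_and_forces, energy_report, resolve_tensions
from .quantify import FoldGeometry, extract_cross_section, measure_fold_geometry

__all__ = [
    "RelaxationError",
    "RelaxReport",
    "relax",
    "RampProtocol",
    "RampStep",
    "run_ramp",
]

RAMP_MODES = ("basal_decrease", "lateral_increase", "apical_increase")


class RelaxationError(RuntimeError):
    """Relaxation failed to reach the force tolerance; carries diagnostics."""

    def __init__(self, message: str, max_force: float, energy_trace: list[float]):
        super().__init__(
            f"{message} (last max force {max_force:.3e}; "
            f"{len(energy_trace)} energy samples recorded)"
        )
        self.max_force = max_force
        self.energy_trace = energy_trace


@dataclass
class RelaxReport:
    converged: bool
    n_iterations: int
    energy: float
    max_force: float
    max_volume_violation: float
    energy_trace: list[float] = field(default_factory=list, repr=False)


def relax(
    mesh: TissueMesh,
    params: MechanicalParams,
    tol: float = 1e-6,
    max_iter: int = 20000,
    n_restarts: int = 8,
) -> tuple[TissueMesh, RelaxReport]:
    """Relax the mesh to a local minimum of W: max vertex force norm < tol.

    Returns a new mesh (input unchanged) and a convergence report.  If the
    input is already at equilibrium it is returned as-is.  Raises
    :class:`RelaxationError` when the iteration budget is exhausted.
    """
    trace: list[float] = []
    last_W = [np.inf]
    resolved = resolve_tensions(mesh, params)

    def fun(x: np.ndarray):
        W, F = energy_and_forces(mesh, params, positions=x, resolved=resolved)
        last_W[0] = W
        return W, -F.ravel()

    def max_force(x: np.ndarray) -> float:
        _, F = energy_and_forces(mesh, params, positions=x, resolved=resolved)
        return float(np.linalg.norm(F, axis=1).max())

    x = mesh.positions.ravel().copy()
    mf0 = max_force(x)
    if mf0 < tol:
        rep = energy_report(mesh, params)
        return mesh, RelaxReport(True, 0, rep["energy"], mf0, rep["max_volume_violation"])

    n_iter = 0
    for attempt in range(n_restarts):
        res = minimize(
            fun,
            x,
            jac=True,
            method="L-BFGS-B",
            callback=lambda xk: trace.append(last_W[0]),
            options=dict(maxiter=max_iter, maxcor=25, ftol=1e-18, gtol=tol * 0.3),
        )
        x = res.x
        n_iter += res.nit
        if max_force(x) < tol:
            break
        # The quadratic descent stalls once energy differences reach machine
        # precision (W is O(C) with a stiff volume penalty while the force
        # tolerance is 1e-6).  Polish by solving F(x) = 0 directly with a
        # matrix-free Newton-Krylov step, which works at gradient precision.
        if True:
            def residual(xr):
                _, F = energy_and_forces(mesh, params, positions=xr, resolved=resolved)
                return F.ravel()

            try:
                sol = root(
                    residual,
                    x,
                    method="krylov",
                    options=dict(fatol=tol * 0.1, maxiter=100, disp=False),
                )
                if np.isfinite(sol.x).all():
                    Wx = energy_and_forces(mesh, params, positions=sol.x, want_grad=False)[0]
                    # accept only if it did not leave the basin
                    if Wx <= last_W[0] + 1e-7 * (1.0 + abs(last_W[0])):
                        x = sol.x
            except Exception:  # pragma: no cover - polish is best-effort
                pass
            if max_force(x) < tol:
                break
    mf = max_force(x)
    if mf >= tol:
        raise RelaxationError("relaxation did not converge", mf, trace)
    out = mesh.with_positions(x)
    rep = energy_report(out, params)
    return out, RelaxReport(True, n_iter, rep["energy"], mf, rep["max_volume_violation"], trace)


# ----------------------------------------------------------------------
@dataclass
class RampProtocol:
    """Incremental tension-rescaling protocol for a cell stripe.

    ``basal_decrease``: T_b' = (1 + delta) T_b and Lambda_b' = (1 + delta)
    Lambda_b with delta <= 0 (plots use -delta).  ``lateral_increase``:
    T_l' = (1 + delta) T_l with delta >= 0.  ``apical_increase`` (control):
    T_a' = (1 + delta) T_a and Lambda_a' = (1 + delta) Lambda_a, delta >= 0.
    """

    mode: str
    grid: np.ndarray
    region: str = PRE_FOLD

    def __post_init__(self) -> None:
        if self.mode not in RAMP_MODES:
            raise ValueError(f"mode must be one of {RAMP_MODES}")
        self.grid = np.asarray(self.grid, dtype=float)
        mags = np.abs(self.grid)
        d = np.diff(mags)
        if len(d) and not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError(
                "grid must be monotone in |delta| (outward ramp or return branch)"
            )
        if self.mode == "basal_decrease":
            if np.any(self.grid > 0) or np.any(1.0 + self.grid < 0):
                raise ValueError("basal_decrease requires -1 <= delta <= 0")
        else:
            if np.any(self.grid < 0):
                raise ValueError(f"{self.mode} requires delta >= 0")

    @classmethod
    def default(cls, mode: str, n_steps: int = 40, magnitude: float | None = None):
        """Default uniform grid: 40 steps to delta_b = -0.8 for the basal
        protocol (the scale of the measured basal recoil reduction in
        pre-fold cells) and to +1.0 for lateral ramps."""
        if magnitude is None:
            magnitude = 0.8 if mode == "basal_decrease" else 1.0
        sign = -1.0 if mode == "basal_decrease" else 1.0
        return cls(mode=mode, grid=sign * np.linspace(0, magnitude, n_steps + 1)[1:])

    def apply(self, params: MechanicalParams, delta: float) -> MechanicalParams:
        """Parameters with the stripe's tensions rescaled by (1 + delta)."""
        p = params.copy()
        ov = dict(p.region_overrides.get(self.region, {}))
        if self.mode == "basal_decrease":
            ov["T_b"] = (1.0 + delta) * params.T_b
            ov["Lambda_b"] = (1.0 + delta) * params.Lambda_b
        elif self.mode == "lateral_increase":
            ov["T_l"] = (1.0 + delta) * params.T_l
        else:  # apical_increase
            ov["T_a"] = (1.0 + delta) * params.T_a
            ov["Lambda_a"] = (1.0 + delta) * params.Lambda_a
        p.region_overrides[self.region] = ov
        return p


@dataclass
class RampStep:
    delta: float
    mesh: TissueMesh
    geometry: FoldGeometry
    energy: float
    max_force: float
    max_volume_violation: float


def _default_section_offset(mesh: TissueMesh) -> float:
    """A plane between lattice vertex columns near the box center, computed
    from the reference (anchor) configuration so it is stable under
    deformation."""
    Lx, _ = mesh.box
    ref = mesh.anchors if mesh.anchors is not None else mesh.positions[: mesh.n_apical]
    xs = np.unique(np.round(ref[:, 0], 9))
    if len(xs) > 1:
        gaps = np.diff(xs)
        k = int(np.argmin(np.abs(xs[:-1] + gaps / 2 - Lx / 2)))
        return float(xs[k] + gaps[k] / 2)
    return Lx / 2


def run_ramp(
    mesh: TissueMesh,
    params: MechanicalParams,
    protocol: RampProtocol,
    tol: float = 1e-6,
    section_offset: float | None = None,
    keep_meshes: bool = True,
) -> list[RampStep]:
    """Quasistatic ramp: for each grid value rescale the stripe tensions,
    re-relax warm-started from the previous equilibrium, and record the
    fold geometry of a cross section through the box center.

    The input mesh must be pre-relaxed at delta = 0.
    """
    offset = _default_section_offset(mesh) if section_offset is None else section_offset
    steps: list[RampStep] = []
    current = mesh
    for delta in protocol.grid:
        p = protocol.apply(params, float(delta))
        try:
            current, rep = relax(current, p, tol=tol)
        except RelaxationError as err:
            raise RelaxationError(
                f"ramp failed at delta={delta:+.4f}: {err}", err.max_force, err.energy_trace
            ) from err
        geom = measure_fold_geometry(extract_cross_section(current, offset=offset))
        steps.append(
            RampStep(
                delta=float(delta),
                mesh=current if keep_meshes else None,
                geometry=geom,
                energy=rep.energy,
                max_force=rep.max_force,
                max_volume_violation=rep.max_volume_violation,
            )
        )
    return steps
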