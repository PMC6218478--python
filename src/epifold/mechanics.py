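"""Mechanical energy of the columnar-epithelium vertex model and its gradient.

The tissue energy is

    W = sum_c T_a(c) A_a(c) + sum_c T_b(c) A_b(c)
      + sum_{lateral faces f} Tbar_l(f) A(f)
      + sum_{apical edges e} LamBar_a(e) L(e)
      + sum_{basal edges e} LamBar_b(e) L(e)
      + sum_{basal vertices i} (k/2) |x_i - X_ref,i|^2
      + sum_c (K_V/2) (V_c - V0_c)^2 / V0_c

where barred tensions on shared lateral faces and edges are the mean of the
parameter over the 1-2 adjacent cells, each shared element counted once.
Volume conservation is imposed as a stiff quadratic penalty (monitored; the
default stiffness keeps the violation below 0.1% in all shipped scenarios).

Forces are minus the exact analytic gradient of every term; they are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import TissueMesh, minimum_image

__all__ = ["MechanicalParams", "total_energy", "forces", "energy_and_forces", "energy_report"]

_TENSION_FIELDS = ("T_a", "T_b", "T_l", "Lambda_a", "Lambda_b")


@dataclass
class MechanicalParams:
    """Nondimensional mechanical parameters.

    Units: the reference apical surface tension is 1 and the cell target
    volume is 1, so lengths are in units of V0^(1/3) and tensions in units
    of T_a.  ``Lambda_hat = Lambda_a / (T_a V0^(1/3))`` and
    ``k_hat = k V0^(1/3) / T_a`` are the two free normalized parameters; both
    default to 1.

    ``region_overrides`` maps a region label to absolute per-cell parameter
    values (used by tension-ramp protocols).  ``edge_overrides`` /
    ``lateral_overrides`` replace the shared-element mean tension of a single
    edge or lateral face (used by in-silico ablation).
    """

    T_a: float = 1.0
    T_b: float = 4.0
    T_l: float = 1.0
    Lambda_a: float = 1.0
    Lambda_b: float = 4.0
    k: float = 1.0
    K_V: float = 2.0e4
    region_overrides: dict = field(default_factory=dict)
    edge_overrides: dict = field(default_factory=dict)
    lateral_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in _TENSION_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.K_V <= 0:
            raise ValueError("K_V must be > 0")

    @classmethod
    def from_normalized(
        cls,
        lambda_hat: float = 1.0,
        k_hat: float = 1.0,
        basal_apical_ratio: float = 4.0,
        T_l: float = 1.0,
        K_V: float = 2.0e4,
    ) -> "MechanicalParams":
        """Build parameters from the two normalized free parameters and the
        basal:apical tension ratio (basal edge *and* surface tensions are the
        ratio times the apical ones)."""
        return cls(
            T_a=1.0,
            T_b=basal_apical_ratio,
            T_l=T_l,
            Lambda_a=lambda_hat,
            Lambda_b=basal_apical_ratio * lambda_hat,
            k=k_hat,
            K_V=K_V,
        )

    def copy(self) -> "MechanicalParams":
        return replace(
            self,
            region_overrides={k: dict(v) for k, v in self.region_overrides.items()},
            edge_overrides=dict(self.edge_overrides),
            lateral_overrides=dict(self.lateral_overrides),
        )

    def cell_arrays(self, mesh: TissueMesh) -> dict[str, np.ndarray]:
        """Per-cell parameter arrays with region overrides applied."""
        C = len(mesh.cells)
        out = {f: np.full(C, getattr(self, f)) for f in _TENSION_FIELDS}
        for ci, cell in enumerate(mesh.cells):
            ov = self.region_overrides.get(cell.region)
            if ov:
                for f, v in ov.items():
                    if f not in out:
                        raise KeyError(f"unknown per-cell parameter {f!r}")
                    out[f][ci] = v
        return out


def _shared_mean(per_cell: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Mean of a per-cell parameter over the 1-2 adjacent cells of each element."""
    vals = per_cell[np.clip(adj, 0, None)]
    valid = adj >= 0
    return (vals * valid).sum(axis=1) / valid.sum(axis=1)


# Kink-smoothing scales for degenerate elements.  With fixed topology a
# contracting fold can drive a junctional edge (a T1-like event) or a fan
# triangle to zero size, where |L| and |n| are non-smooth and no interior
# force balance exists.  sqrt(x^2 + eps^2) regularizes both; the energy
# offset is O(eps^2 / size) away from degeneracy and O(eps) at it, far below
# every tolerance used in analysis.  Values live in _kernels (compiled path).
from ._kernels import EPS_AREA, EPS_EDGE, energy_grad as _energy_grad_kernel


class _Topology:
    """Cached integer tables and frozen periodic-wrap shifts.

    The wrap offsets (integer multiples of the box vectors placing every
    face/edge vertex in a contiguous frame) are computed once from the
    reference configuration and kept fixed: topology never changes and cells
    never migrate across the box, so freezing them keeps the energy a smooth
    function of the positions however large the fold deformation grows.
    """

    def __init__(self, mesh: TissueMesh) -> None:
        sizes = set(mesh.cell_sizes.tolist())
        if len(sizes) != 1:
            raise ValueError("mechanics requires a uniform cell cycle length")
        self.m = sizes.pop()
        self.cycA = np.array([c.apical for c in mesh.cells])  # (C, m)
        self.cycB = self.cycA + mesh.n_apical
        self.lat = mesh.lateral_faces  # (L, 4)
        self.lat_cells = mesh.lateral_cells
        self.edgesA = mesh.apical_edges
        self.edgesB = mesh.basal_edges
        self.edge_cells = mesh.edge_cells
        self.V0 = np.array([c.target_volume for c in mesh.cells])

        X0, box = mesh.positions, mesh.box

        def frozen_shift(idx: np.ndarray, ref: np.ndarray) -> np.ndarray:
            d = X0[idx] - ref
            return minimum_image(d, box) - d

        refA = X0[self.cycA[:, :1]]
        self.shiftA = frozen_shift(self.cycA, refA)
        self.shiftB = frozen_shift(self.cycB, refA)
        self.shiftL = frozen_shift(self.lat, X0[self.lat[:, :1]])
        dA = X0[self.edgesA[:, 1]] - X0[self.edgesA[:, 0]]
        self.shiftEa = minimum_image(dA, box) - dA
        dB = X0[self.edgesB[:, 1]] - X0[self.edgesB[:, 0]]
        self.shiftEb = minimum_image(dB, box) - dB

        self.kn = (np.arange(self.m) + 1) % self.m
        # one flat scatter index for all gradient contributions (bincount)
        self.scatter_idx = np.concatenate(
            [
                self.cycA.ravel(),
                self.cycB.ravel(),
                self.lat.ravel(),
                self.edgesA[:, 1],
                self.edgesA[:, 0],
                self.edgesB[:, 1],
                self.edgesB[:, 0],
            ]
        )


def _topology(mesh: TissueMesh) -> _Topology:
    topo = getattr(mesh, "_mech_topo", None)
    if topo is None:
        topo = _Topology(mesh)
        mesh._mech_topo = topo
    return topo


def resolve_tensions(mesh: TissueMesh, params: MechanicalParams) -> tuple:
    """Per-element effective tensions: per-cell apical/basal surface tension,
    per-lateral-face and per-edge shared means, with ablation overrides
    applied.  Precompute once when evaluating many configurations under
    fixed parameters (relaxation, recoil integration)."""
    topo = _topology(mesh)
    per_cell = params.cell_arrays(mesh)
    T_lat = _shared_mean(per_cell["T_l"], topo.lat_cells)
    for fi, v in params.lateral_overrides.items():
        if not 0 <= fi < len(T_lat):
            raise KeyError(f"unknown lateral face {fi}")
        T_lat[fi] = v
    lam = {}
    for layer, fieldname in (("apical", "Lambda_a"), ("basal", "Lambda_b")):
        lam[layer] = _shared_mean(per_cell[fieldname], topo.edge_cells)
        for (ov_layer, e), v in params.edge_overrides.items():
            if ov_layer == layer:
                if not 0 <= e < len(lam[layer]):
                    raise KeyError(f"unknown {layer} edge {e}")
                lam[layer][e] = v
    anchors = mesh.anchors
    k = params.k
    if anchors is None:
        anchors = np.zeros((0, 3))
        k = 0.0
    return (per_cell["T_a"], per_cell["T_b"], T_lat, lam["apical"], lam["basal"], k, anchors)


def energy_and_forces(
    mesh: TissueMesh,
    params: MechanicalParams,
    positions: np.ndarray | None = None,
    want_grad: bool = True,
    breakdown: bool = False,
    resolved: tuple | None = None,
):
    """Total energy W and per-vertex forces (-dW/dx).

    Returns ``(W, F)`` where ``F`` is (n_vertices, 3), or
    ``(W, F, parts, volumes)`` when ``breakdown`` is true.  ``resolved`` may
    carry the output of :func:`resolve_tensions` to skip re-resolving
    per-element tensions in tight loops.
    """
    topo = _topology(mesh)
    X = mesh.positions if positions is None else np.ascontiguousarray(
        positions, dtype=float
    ).reshape(-1, 3)
    if resolved is None:
        resolved = resolve_tensions(mesh, params)
    T_a, T_b, T_lat, lam_a, lam_b, k, anchors = resolved

    W, G, V, parts_arr = _energy_grad_kernel(
        X,
        topo.cycA,
        topo.cycB,
        topo.shiftA,
        topo.shiftB,
        topo.lat,
        topo.shiftL,
        topo.edgesA,
        topo.shiftEa,
        topo.edgesB,
        topo.shiftEb,
        T_a,
        T_b,
        T_lat,
        lam_a,
        lam_b,
        topo.V0,
        params.K_V,
        k,
        anchors,
        mesh.n_apical,
    )
    if breakdown:
        parts = dict(
            zip(
                (
                    "apical_surface",
                    "basal_surface",
                    "lateral_surface",
                    "apical_edges",
                    "basal_edges",
                    "ecm_springs",
                    "volume_penalty",
                ),
                parts_arr.tolist(),
            )
        )
        return W, -G, parts, V
    if want_grad:
        return W, -G
    return W, None


def total_energy(mesh: TissueMesh, params: MechanicalParams) -> float:
    """Tissue energy W (see module docstring for the functional)."""
    W, _ = energy_and_forces(mesh, params, want_grad=False)
    return W


def forces(mesh: TissueMesh, params: MechanicalParams) -> np.ndarray:
    """Force on every vertex, -dW/dx, shape (n_vertices, 3)."""
    _, F = energy_and_forces(mesh, params)
    return F


def energy_report(mesh: TissueMesh, params: MechanicalParams) -> dict:
    """Energy breakdown, max force norm, and cell-volume violation."""
    W, F, parts, V = energy_and_forces(mesh, params, breakdown=True)
    topo = _topology(mesh)
    viol = np.abs(V - topo.V0) / topo.V0
    return {
        "energy": W,
        "parts": parts,
        "max_force": float(np.linalg.norm(F, axis=1).max()),
        "volumes": V,
        "max_volume_violation": float(viol.max()),
    }


def cell_volumes(mesh: TissueMesh, params: MechanicalParams | None = None) -> np.ndarray:
    """Closed-surface volumes of all cells (same triangulation as the energy)."""
    p = params or MechanicalParams()
    _, _, _, V = energy_and_forces(mesh, p, breakdown=True)
    return V
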