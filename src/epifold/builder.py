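"""Construction of the initial periodic columnar packing.

The reference tissue is a regular hexagonal-prism packing of identical
cells with unit volume on a periodic box, relaxed to mechanical equilibrium
with basal edge and surface tensions four times the apical ones by default.
The box is sized so that the cell aspect ratio (height over in-plane
diameter, 2*sqrt(A_a/pi)) matches a requested target, and the lateral
surface tension is calibrated so the flat packing carries no in-plane
tissue stress (the flat state would be an equilibrium even with a free
box).  ECM anchor points are set to the relaxed basal vertex positions, so
springs are at rest in the reference state.
"""

from __future__ import annotations

import numpy as np

from .equilibration import relax
from .geometry import NEIGHBOR, PRE_FOLD, Cell, TissueMesh
from .mechanics import MechanicalParams

__all__ = ["build_hex_tissue", "assign_stripe", "calibrated_lateral_tension", "hex_dimensions"]

# pointy-top hexagon corner offsets from the cell center, CCW from the top,
# in lattice units (sqrt(3) s / 2 along x, s / 2 along y)
_CORNERS = [(0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1), (1, 1)]


def hex_dimensions(aspect_ratio: float, target_volume: float = 1.0) -> tuple[float, float, float]:
    """Hexagon side s, cross-section area A and height h of a regular
    hexagonal prism of the given volume and aspect ratio h / (2 sqrt(A/pi))."""
    if aspect_ratio <= 0:
        raise ValueError("aspect_ratio must be > 0")
    A = (np.sqrt(np.pi) * target_volume / (2.0 * aspect_ratio)) ** (2.0 / 3.0)
    s = float(np.sqrt(A / (1.5 * np.sqrt(3.0))))
    h = target_volume / A
    return s, float(A), float(h)


def calibrated_lateral_tension(
    params: MechanicalParams, s: float, target_volume: float = 1.0
) -> float:
    """Lateral tension making the flat regular packing stress-free.

    Stationarity of the per-cell energy of a regular hexagonal prism of
    fixed volume with respect to the hexagon side s gives
    T_l = sqrt(3) s^2 [3 sqrt(3) s (T_a + T_b) + 3 (Lambda_a + Lambda_b)] / (2 V0).
    """
    num = 3.0 * np.sqrt(3.0) * s * (params.T_a + params.T_b) + 3.0 * (
        params.Lambda_a + params.Lambda_b
    )
    return float(np.sqrt(3.0) * s**2 * num / (2.0 * target_volume))


def build_hex_tissue(
    nx: int,
    ny: int,
    aspect_ratio: float = 5.0,
    params: MechanicalParams | None = None,
    calibrate: bool = True,
    perturb_amplitude: float = 0.0,
    seed: int | None = None,
    tol: float = 1e-6,
) -> tuple[TissueMesh, MechanicalParams]:
    """Build and relax an nx-by-ny periodic hexagonal columnar packing.

    ``ny`` must be even (periodic hexagonal tiling parity); both dimensions
    must be at least 4 so that a stripe can have far neighbors.  A small
    seeded vertex perturbation (``perturb_amplitude`` in length units,
    applied after the reference state is anchored) models replicate-to-
    replicate packing variation.

    Returns the relaxed mesh together with the (possibly re-calibrated)
    parameters; the achieved aspect ratio is stored in ``mesh.meta``.
    """
    if nx < 4 or ny < 4:
        raise ValueError("nx and ny must be >= 4")
    if ny % 2:
        raise ValueError("ny must be even for a periodic hexagonal tiling")
    params = (params or MechanicalParams()).copy()
    s, A, h = hex_dimensions(aspect_ratio)
    if calibrate:
        params.T_l = calibrated_lateral_tension(params, s)

    ux, uy = np.sqrt(3.0) * s / 2.0, s / 2.0
    Umax, Vmax = 2 * nx, 3 * ny
    box = (Umax * ux, Vmax * uy)

    vert_ids: dict[tuple[int, int], int] = {}

    def vid(u: int, v: int) -> int:
        key = (u % Umax, v % Vmax)
        if key not in vert_ids:
            vert_ids[key] = len(vert_ids)
        return vert_ids[key]

    cells_idx: list[tuple[int, int, list[int]]] = []
    for iy in range(ny):
        for ix in range(nx):
            uc = 2 * ix + (iy % 2)
            vc = 3 * iy + 2
            cyc = [vid(uc + du, vc + dv) for du, dv in _CORNERS]
            cells_idx.append((ix, iy, cyc))

    na = len(vert_ids)
    assert na == 2 * nx * ny, "hexagonal lattice vertex count mismatch"
    apical = np.zeros((na, 3))
    for (u, v), i in vert_ids.items():
        apical[i] = (u * ux, v * uy, h)
    basal = apical.copy()
    basal[:, 2] = 0.0
    positions = np.vstack([apical, basal])

    cells = [
        Cell(
            id=ci,
            apical=np.array(cyc),
            basal=np.array(cyc) + na,
            region=NEIGHBOR,
            row=iy,
            col=ix,
            target_volume=1.0,
        )
        for ci, (ix, iy, cyc) in enumerate(cells_idx)
    ]
    mesh = TissueMesh(positions, cells, box)

    # relax the reference state without springs (anchors not yet defined)
    p0 = params.copy()
    p0.k = 0.0
    mesh, _ = relax(mesh, p0, tol=tol)
    mesh.anchors = mesh.positions[na:].copy()

    if perturb_amplitude > 0.0:
        rng = np.random.default_rng(seed)
        mesh = mesh.with_positions(
            mesh.positions + perturb_amplitude * rng.standard_normal(mesh.positions.shape)
        )
        mesh, _ = relax(mesh, params, tol=tol)

    from .mechanics import energy_and_forces  # local import to avoid cycle noise

    _, _, _, volumes = energy_and_forces(mesh, params, breakdown=True)
    A_meas = volumes.mean() / (mesh.positions[:na, 2].mean() - mesh.positions[na:, 2].mean())
    h_meas = float(mesh.positions[:na, 2].mean() - mesh.positions[na:, 2].mean())
    aspect = h_meas / (2.0 * np.sqrt(A_meas / np.pi))
    mesh.meta = {
        "nx": nx,
        "ny": ny,
        "side": s,
        "height": h_meas,
        "aspect_ratio_target": aspect_ratio,
        "aspect_ratio_achieved": float(aspect),
    }
    if abs(aspect - aspect_ratio) / aspect_ratio > 0.02:
        raise RuntimeError(
            f"calibration missed the target aspect ratio: achieved {aspect:.3f}, "
            f"target {aspect_ratio:.3f}"
        )
    return mesh, params


def assign_stripe(mesh: TissueMesh, width: int, axis: str = "x") -> TissueMesh:
    """Label a centered contiguous stripe of ``width`` cell rows as pre-fold.

    The stripe runs along ``axis`` (only 'x' is supported: rows are indexed
    along y).  Remaining cells are labelled neighbor.  Returns the mesh
    (labels modified in place).
    """
    if axis != "x":
        raise ValueError("only stripes running along x are supported")
    rows = [c.row for c in mesh.cells if c.row is not None]
    if not rows:
        raise ValueError("mesh cells carry no row indices")
    ny = max(rows) + 1
    if not 1 <= width < ny:
        raise ValueError(f"stripe width must satisfy 1 <= width < {ny}")
    r0 = (ny - width) // 2
    stripe = set(range(r0, r0 + width))
    for c in mesh.cells:
        c.region = PRE_FOLD if c.row in stripe else NEIGHBOR
    return mesh
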