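"""Mesh data model and geometric primitives for a columnar epithelium.

The tissue is represented by paired apical and basal vertex sheets on a
domain that is periodic in x and y and free in z.  Each cell is a prism
bounded by an apical polygon, a basal polygon (same cyclic order, vertex
``i`` apical paired with vertex ``i + n_apical`` basal), and quadrilateral
lateral faces shared with its neighbours.  Topology is fixed for the whole
simulation: folds form by vertex displacement only, with no neighbour
exchanges, divisions, or extrusions.

Conventions
-----------
* Lengths are measured in units of the cell target volume to the power 1/3.
* z increases from basal to apical in the flat reference state; an apical
  indentation is a negative z-displacement of apical fold vertices.
* Non-planar faces are triangulated by a fan about the face centroid
  (mean of the cycle vertices).  Areas and cell volumes use the *same*
  triangulation so that volume gradients are consistent with area gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

APICAL = "apical"
BASAL = "basal"
PRE_FOLD = "pre_fold"
NEIGHBOR = "neighbor"

__all__ = [
    "Cell",
    "TissueMesh",
    "minimum_image",
    "unwrap_cycle",
    "face_area",
    "cell_volume",
    "edge_length",
    "PRE_FOLD",
    "NEIGHBOR",
    "APICAL",
    "BASAL",
]


def minimum_image(d: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Wrap displacement vectors ``d`` (..., 3) to the nearest periodic image.

    Only x and y are periodic; z is left untouched.
    """
    d = np.array(d, dtype=float, copy=True)
    for ax, L in enumerate(box):
        d[..., ax] -= L * np.round(d[..., ax] / L)
    return d


def unwrap_cycle(positions: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Unwrap a vertex cycle (m, 3) by minimum image relative to its first vertex."""
    p0 = positions[..., :1, :]
    return p0 + minimum_image(positions - p0, box)


@dataclass
class Cell:
    """A prismatic cell: paired apical/basal vertex cycles plus metadata.

    ``basal[k]`` must be the basal partner of ``apical[k]`` (columnar pairing).
    ``row`` records the cell-row index assigned by the tissue builder and is
    used to measure distance from the pre-fold stripe.
    """

    id: int
    apical: np.ndarray
    basal: np.ndarray
    region: str = NEIGHBOR
    row: int | None = None
    col: int | None = None
    target_volume: float = 1.0

    def __post_init__(self) -> None:
        self.apical = np.asarray(self.apical, dtype=np.int64)
        self.basal = np.asarray(self.basal, dtype=np.int64)
        if self.apical.ndim != 1 or len(self.apical) < 3:
            raise ValueError("apical cycle must have length >= 3")
        if len(self.apical) != len(self.basal):
            raise ValueError("apical and basal cycles must have equal length")
        if len(set(self.apical.tolist())) != len(self.apical):
            raise ValueError(f"cell {self.id}: repeated vertex in apical cycle")
        if len(set(self.basal.tolist())) != len(self.basal):
            raise ValueError(f"cell {self.id}: repeated vertex in basal cycle")


class TissueMesh:
    """Periodic columnar tissue mesh: the full simulation state.

    Parameters
    ----------
    positions
        (2 * n_apical, 3) array; rows ``[0, n_apical)`` are apical vertices,
        rows ``[n_apical, 2 n_apical)`` their basal partners.
    cells
        List of :class:`Cell`.  Every cell's basal cycle must equal its apical
        cycle shifted by ``n_apical``.
    box
        Periodic dimensions (Lx, Ly); z is aperiodic.
    anchors
        (n_apical, 3) ECM reference points, one per basal vertex (indexed by
        the basal vertex's local index ``global - n_apical``), or ``None``
        before the reference state has been relaxed.
    """

    def __init__(
        self,
        positions: np.ndarray,
        cells: Sequence[Cell],
        box: tuple[float, float],
        n_apical: int | None = None,
        anchors: np.ndarray | None = None,
    ) -> None:
        self.positions = np.array(positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        n = self.positions.shape[0]
        if n % 2:
            raise ValueError("vertex count must be even (apical/basal pairing)")
        self.n_apical = n // 2 if n_apical is None else int(n_apical)
        if 2 * self.n_apical != n:
            raise ValueError("positions must hold exactly paired apical+basal vertices")
        self.cells = list(cells)
        self.box = (float(box[0]), float(box[1]))
        self.anchors = None if anchors is None else np.array(anchors, dtype=float)
        if self.anchors is not None and self.anchors.shape != (self.n_apical, 3):
            raise ValueError("anchors must be (n_apical, 3)")
        self.meta: dict = {}
        self._build_topology()

    # ------------------------------------------------------------------
    # topology tables (fixed for the lifetime of the mesh)
    # ------------------------------------------------------------------
    def _build_topology(self) -> None:
        na = self.n_apical
        for c in self.cells:
            if np.any(c.apical >= na) or np.any(c.apical < 0):
                raise ValueError(f"cell {c.id}: apical indices out of range")
            if not np.array_equal(c.basal, c.apical + na):
                raise ValueError(
                    f"cell {c.id}: basal cycle must be the apical cycle's "
                    "partner vertices in the same cyclic order"
                )

        # undirected apical edges -> adjacent cells, and which cell traverses i->j
        edge_cells: dict[tuple[int, int], list[int]] = {}
        edge_forward: dict[tuple[int, int], list[int]] = {}
        for ci, c in enumerate(self.cells):
            cyc = c.apical
            for k in range(len(cyc)):
                i, j = int(cyc[k]), int(cyc[(k + 1) % len(cyc)])
                key = (min(i, j), max(i, j))
                edge_cells.setdefault(key, []).append(ci)
                edge_forward.setdefault(key, []).append(ci if i == key[0] else -1)
        for key, cs in edge_cells.items():
            if len(cs) > 2:
                raise ValueError(f"edge {key} bordered by more than two cells")

        keys = sorted(edge_cells)
        self.apical_edges = np.array(keys, dtype=np.int64).reshape(-1, 2)
        self.basal_edges = self.apical_edges + na
        self.edge_cells = np.full((len(keys), 2), -1, dtype=np.int64)
        for e, key in enumerate(keys):
            cs = edge_cells[key]
            self.edge_cells[e, : len(cs)] = cs

        # one lateral quad per apical edge: (a_i, a_j, b_j, b_i), i < j
        self.lateral_faces = np.column_stack(
            [
                self.apical_edges[:, 0],
                self.apical_edges[:, 1],
                self.basal_edges[:, 1],
                self.basal_edges[:, 0],
            ]
        )
        self.lateral_cells = self.edge_cells.copy()

        edge_index = {key: e for e, key in enumerate(keys)}
        m_max = max(len(c.apical) for c in self.cells)
        C = len(self.cells)
        # lateral face bordering slot k of each cell, and the orientation sign
        # of that face's stored cycle as seen from the cell (+1 = outward).
        self.cell_lateral = np.full((C, m_max), -1, dtype=np.int64)
        self.cell_lateral_sign = np.zeros((C, m_max))
        self.cell_sizes = np.array([len(c.apical) for c in self.cells], dtype=np.int64)
        for ci, c in enumerate(self.cells):
            cyc = c.apical
            for k in range(len(cyc)):
                i, j = int(cyc[k]), int(cyc[(k + 1) % len(cyc)])
                key = (min(i, j), max(i, j))
                self.cell_lateral[ci, k] = edge_index[key]
                # stored quad runs a_min -> a_max; if the cell traverses the
                # edge in that same direction its fan normal points inward
                self.cell_lateral_sign[ci, k] = -1.0 if i == key[0] else 1.0

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    def basal_index(self, apical_index: int) -> int:
        return apical_index + self.n_apical

    def copy(self) -> "TissueMesh":
        m = TissueMesh.__new__(TissueMesh)
        m.positions = self.positions.copy()
        m.n_apical = self.n_apical
        m.cells = self.cells  # topology & labels shared (fixed topology)
        m.box = self.box
        m.anchors = None if self.anchors is None else self.anchors.copy()
        m.meta = dict(self.meta)
        for name in (
            "apical_edges",
            "basal_edges",
            "edge_cells",
            "lateral_faces",
            "lateral_cells",
            "cell_lateral",
            "cell_lateral_sign",
            "cell_sizes",
        ):
            setattr(m, name, getattr(self, name))
        # mechanics caches frozen periodic-wrap offsets keyed to the reference
        # configuration; copies (relaxation steps) must keep using them
        if hasattr(self, "_mech_topo"):
            m._mech_topo = self._mech_topo
        return m

    def with_positions(self, positions: np.ndarray) -> "TissueMesh":
        m = self.copy()
        m.positions = np.array(positions, dtype=float).reshape(-1, 3)
        return m

    def region_cells(self, region: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.cells) if c.region == region])

    # convenience views used by quantification -------------------------------
    def cell_cycles(self, layer: str = APICAL) -> list[np.ndarray]:
        if layer == APICAL:
            return [c.apical for c in self.cells]
        return [c.basal for c in self.cells]


# ----------------------------------------------------------------------
# geometric primitives
# ----------------------------------------------------------------------
def face_area(
    cycle: Iterable[int], positions: np.ndarray, box: tuple[float, float]
) -> float:
    """Area of a (possibly non-planar) face by centroid-fan triangulation.

    The cycle is unwrapped by minimum image relative to its first vertex,
    then triangulated about the centroid; exact for planar polygons.
    """
    cyc = np.asarray(list(cycle), dtype=np.int64)
    if len(cyc) < 3:
        raise ValueError("cycle length must be >= 3")
    if len(set(cyc.tolist())) != len(cyc):
        raise ValueError("degenerate cycle: repeated vertex")
    p = unwrap_cycle(positions[cyc], box)
    c = p.mean(axis=0)
    a = p - c
    b = np.roll(p, -1, axis=0) - c
    n = np.cross(a, b)
    return float(0.5 * np.linalg.norm(n, axis=1).sum())


def edge_length(
    edge: tuple[int, int], positions: np.ndarray, box: tuple[float, float]
) -> float:
    """Euclidean length of an edge under the minimum-image convention."""
    i, j = edge
    d = minimum_image(positions[j] - positions[i], box)
    return float(np.linalg.norm(d))


def _cell_local_coords(
    cell: Cell, positions: np.ndarray, box: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Apical and basal cycle coordinates unwrapped around the cell's first
    apical vertex (consistent frame for the closed cell surface)."""
    ref = positions[cell.apical[0]]
    qa = ref + minimum_image(positions[cell.apical] - ref, box)
    qb = ref + minimum_image(positions[cell.basal] - ref, box)
    return qa, qb


def _fan_signed_volume(pts: np.ndarray) -> float:
    """Signed volume contribution (divergence theorem) of a centroid-fan
    triangulated face with vertex loop ``pts`` (m, 3)."""
    c = pts.mean(axis=0)
    cross_sum = np.cross(pts, np.roll(pts, -1, axis=0)).sum(axis=0)
    return float(np.dot(c, cross_sum)) / 6.0


def cell_volume(cell: Cell, positions: np.ndarray, box: tuple[float, float]) -> float:
    """Volume of a cell via the divergence theorem over its closed surface.

    The surface is the apical face (outward normal pointing apically for a
    counter-clockwise apical cycle viewed from above), the basal face
    (reversed), and the lateral quads; all faces fan-triangulated about their
    centroids.  Positive for correctly oriented cells.
    """
    qa, qb = _cell_local_coords(cell, positions, box)
    m = len(cell.apical)
    vol = _fan_signed_volume(qa)  # apical, outward = +z when flat
    vol -= _fan_signed_volume(qb)  # basal face reversed
    for k in range(m):
        kn = (k + 1) % m
        quad = np.array([qa[kn], qa[k], qb[k], qb[kn]])  # outward for CCW apical
        vol += _fan_signed_volume(quad)
    return vol
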