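"""Fold-shape readout from cross sections, and per-cell intensity ratios.

The geometric readout mirrors manual tracking of labelled cells in y-z
cross sections perpendicular to a fold: apical indentation depth ``d_a``,
signed basal deformation ``d_b``, mean apical/basal cross-sectional lengths
``l_a``/``l_b`` of the fold-center cells, and the apico-basal height
``h_tissue`` of cells outside the fold, which normalizes all other lengths.

Sign conventions (ours, fixed):
* ``d_a > 0``: the apical surface of fold cells dips below the apical plane
  of the neighboring tissue (apical indentation).
* ``d_b > 0``: the basal surface of fold cells bulges outward, away from the
  apical side; ``d_b < 0`` is a basal indentation.

The "neighbors' plane" is a least-squares line through the apical (or basal)
section vertices of neighbor cells at least ``min_neighbor_dist`` cell rows
away from the fold, mirroring the use of cells outside the fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PRE_FOLD, TissueMesh, minimum_image

__all__ = [
    "SectionCell",
    "CrossSection",
    "FoldGeometry",
    "extract_cross_section",
    "measure_fold_geometry",
    "intensity_ratio",
]

FOLD_CENTER = "fold_center"
NEIGHBOR = "neighbor"


@dataclass
class SectionCell:
    """One cell's trace in a 2D (y, z) cross section."""

    cell_id: int
    label: str  # 'fold_center' | 'neighbor'
    dist: int  # cell-row distance from the fold center (0 = fold cell)
    apical: np.ndarray  # (2, 2) segment endpoints (y, z)
    basal: np.ndarray  # (2, 2)

    def __post_init__(self) -> None:
        self.apical = np.asarray(self.apical, dtype=float).reshape(2, 2)
        self.basal = np.asarray(self.basal, dtype=float).reshape(2, 2)


@dataclass
class CrossSection:
    """Per-cell apical/basal segments plus tissue outlines in a section plane."""

    cells: list[SectionCell]
    apical_outline: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    basal_outline: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    axis: str = "x"
    offset: float = float("nan")

    def group(self, label: str) -> list[SectionCell]:
        return [c for c in self.cells if c.label == label]


@dataclass
class FoldGeometry:
    """Fold-shape parameters of one cross section (length units of the mesh)."""

    d_a: float
    d_b: float
    l_a: float
    l_b: float
    h_tissue: float

    def __post_init__(self) -> None:
        if not self.h_tissue > 0:
            raise ValueError("h_tissue must be > 0")

    @property
    def d_a_norm(self) -> float:
        return self.d_a / self.h_tissue

    @property
    def d_b_norm(self) -> float:
        return self.d_b / self.h_tissue

    @property
    def l_a_norm(self) -> float:
        return self.l_a / self.h_tissue

    @property
    def l_b_norm(self) -> float:
        return self.l_b / self.h_tissue

    def as_dict(self) -> dict[str, float]:
        return {
            "d_a": self.d_a,
            "d_b": self.d_b,
            "l_a": self.l_a,
            "l_b": self.l_b,
            "h_tissue": self.h_tissue,
            "d_a_norm": self.d_a_norm,
            "d_b_norm": self.d_b_norm,
            "l_a_norm": self.l_a_norm,
            "l_b_norm": self.l_b_norm,
        }


# ----------------------------------------------------------------------
def _plane_crossings(poly: np.ndarray, x0: float) -> list[np.ndarray]:
    """Intersection points of a closed polygon (m, 3) with the plane x = x0."""
    pts = []
    m = len(poly)
    for k in range(m):
        p, q = poly[k], poly[(k + 1) % m]
        dp, dq = p[0] - x0, q[0] - x0
        if dp == 0.0:  # vertex exactly on the plane
            pts.append(p.copy())
        elif dp * dq < 0.0:
            t = dp / (dp - dq)
            pts.append(p + t * (q - p))
    # deduplicate (vertex-on-plane gives the point twice via adjacent edges)
    uniq: list[np.ndarray] = []
    for p in pts:
        if not any(np.allclose(p, u, atol=1e-12) for u in uniq):
            uniq.append(p)
    return uniq


def _row_distance(mesh: TissueMesh) -> dict[int, int]:
    """Periodic cell-row distance of every cell from the pre-fold stripe."""
    rows = sorted({c.row for c in mesh.cells if c.row is not None})
    stripe_rows = {c.row for c in mesh.cells if c.region == PRE_FOLD and c.row is not None}
    out: dict[int, int] = {}
    ny = (max(rows) + 1) if rows else 0
    for ci, c in enumerate(mesh.cells):
        if c.region == PRE_FOLD:
            out[ci] = 0
        elif c.row is None or not stripe_rows:
            out[ci] = 99
        else:
            out[ci] = min(
                min(abs(c.row - r), ny - abs(c.row - r)) for r in stripe_rows
            )
    return out


def extract_cross_section(mesh: TissueMesh, axis: str = "x", offset: float = 0.0) -> CrossSection:
    """Slice the tissue with the plane ``axis = offset`` (y-z section for
    ``axis='x'``, perpendicular to a stripe running along x).

    Emits one apical and one basal 2D segment per intersected cell, labelled
    ``fold_center`` for pre-fold cells, plus ordered tissue outlines.
    """
    if axis != "x":
        raise ValueError("only sections perpendicular to x (y-z planes) are supported")
    Lx, Ly = mesh.box
    dist = _row_distance(mesh)
    cells_out: list[SectionCell] = []
    X = mesh.positions
    for ci, cell in enumerate(mesh.cells):
        ref = X[cell.apical[0]]
        qa = ref + minimum_image(X[cell.apical] - ref, mesh.box)
        qb = ref + minimum_image(X[cell.basal] - ref, mesh.box)
        # nearest periodic image of the plane to this cell
        x0 = offset + Lx * np.round((ref[0] - offset) / Lx)
        pa = _plane_crossings(qa, x0)
        pb = _plane_crossings(qb, x0)
        if len(pa) != 2 or len(pb) != 2:
            continue
        label = FOLD_CENTER if cell.region == PRE_FOLD else NEIGHBOR
        cells_out.append(
            SectionCell(
                cell_id=cell.id,
                label=label,
                dist=dist[ci],
                apical=np.array([[p[1], p[2]] for p in pa]),
                basal=np.array([[p[1], p[2]] for p in pb]),
            )
        )
    if not cells_out:
        raise ValueError(f"section plane x={offset} does not intersect the mesh")

    # re-center y about the fold (periodic direction) so outlines are contiguous
    fold = [c for c in cells_out if c.label == FOLD_CENTER]
    y_ref = (
        float(np.mean([c.apical[:, 0].mean() for c in fold]))
        if fold
        else float(np.mean([c.apical[:, 0].mean() for c in cells_out]))
    )
    for c in cells_out:
        y0 = c.apical[0, 0]
        for seg in (c.apical, c.basal):  # make the cell contiguous about y0
            seg[:, 0] = y0 + (seg[:, 0] - y0) - Ly * np.round((seg[:, 0] - y0) / Ly)
        mid = 0.25 * (c.apical[:, 0].sum() + c.basal[:, 0].sum())
        shift = -Ly * np.round((mid - y_ref) / Ly)
        c.apical[:, 0] += shift
        c.basal[:, 0] += shift

    def outline(which: str) -> np.ndarray:
        pts = np.vstack([getattr(c, which) for c in cells_out])
        return pts[np.argsort(pts[:, 0])]

    return CrossSection(
        cells=cells_out,
        apical_outline=outline("apical"),
        basal_outline=outline("basal"),
        axis=axis,
        offset=offset,
    )


def _fit_line(pts: np.ndarray) -> np.ndarray:
    """Least-squares line z = a + b*y through (n, 2) points; degenerate y
    spread falls back to the horizontal mean."""
    y, z = pts[:, 0], pts[:, 1]
    if np.ptp(y) < 1e-12:
        return np.array([float(np.mean(z)), 0.0])
    b, a = np.polyfit(y, z, 1)
    return np.array([a, b])


def measure_fold_geometry(
    section: CrossSection, min_neighbor_dist: int = 2
) -> FoldGeometry:
    """Fold-shape parameters of a cross section.

    ``d_a`` is the neighbors' apical plane (least-squares line through apical
    vertices of neighbor cells >= ``min_neighbor_dist`` rows from the fold)
    minus the lowest apical z of the fold cells; ``d_b`` is the signed
    extremal deviation of the fold cells' basal vertices from the neighbors'
    basal plane (outward positive); ``l_a``/``l_b`` are mean fold-cell
    segment lengths and ``h_tissue`` the mean apico-basal midpoint distance
    of the far neighbors.
    """
    fold = section.group(FOLD_CENTER)
    if not fold:
        raise ValueError("section has no fold_center cells")
    neighbors = section.group(NEIGHBOR)
    y_fold = np.concatenate([c.apical[:, 0] for c in fold])
    left = [c for c in neighbors if c.apical[:, 0].mean() < y_fold.min()]
    right = [c for c in neighbors if c.apical[:, 0].mean() > y_fold.max()]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 neighbor cells on each side of the fold")
    far = [c for c in neighbors if c.dist >= min_neighbor_dist]
    if len(far) < 2:
        raise ValueError(
            f"need >= 2 neighbor cells at distance >= {min_neighbor_dist} rows"
        )

    ap_plane = _fit_line(np.vstack([c.apical for c in far]))
    ba_plane = _fit_line(np.vstack([c.basal for c in far]))

    fold_ap = np.vstack([c.apical for c in fold])
    fold_ba = np.vstack([c.basal for c in fold])
    i_min = int(np.argmin(fold_ap[:, 1]))
    d_a = float(ap_plane[0] + ap_plane[1] * fold_ap[i_min, 0] - fold_ap[i_min, 1])

    dev = ba_plane[0] + ba_plane[1] * fold_ba[:, 0] - fold_ba[:, 1]
    d_b = float(dev[np.argmax(np.abs(dev))])

    l_a = float(np.mean([np.linalg.norm(c.apical[1] - c.apical[0]) for c in fold]))
    l_b = float(np.mean([np.linalg.norm(c.basal[1] - c.basal[0]) for c in fold]))
    # apico-basal height along z (the apico-basal axis of the section frame)
    h = float(np.mean([c.apical[:, 1].mean() - c.basal[:, 1].mean() for c in far]))
    return FoldGeometry(d_a=d_a, d_b=d_b, l_a=l_a, l_b=l_b, h_tissue=h)


# ----------------------------------------------------------------------
_FOLD_LABELS = {"fold", "fold_center", "pre_fold"}


def intensity_ratio(
    intensities: np.ndarray,
    labels,
    n_boot: int = 0,
    seed: int = 0,
    ci: float = 0.95,
):
    """Ratio of mean per-cell intensity, fold cells over neighbor cells.

    Returns the ratio, or ``(ratio, (lo, hi))`` with a bootstrap-over-cells
    confidence interval when ``n_boot > 0``.
    """
    x = np.asarray(intensities, dtype=float)
    lab = np.asarray(labels)
    if np.any(x < 0):
        raise ValueError("intensities must be >= 0")
    fold = x[np.isin(lab, list(_FOLD_LABELS))]
    neigh = x[lab == "neighbor"]
    if len(fold) == 0 or len(neigh) == 0:
        raise ValueError("both fold and neighbor groups must be non-empty")
    ratio = float(fold.mean() / neigh.mean())
    if n_boot <= 0:
        return ratio
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = (
            rng.choice(fold, len(fold)).mean() / rng.choice(neigh, len(neigh)).mean()
        )
    alpha = (1.0 - ci) / 2.0
    return ratio, (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))
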