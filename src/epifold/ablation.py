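"""In-silico laser ablation and the recoil-velocity estimator.

Ablating an element sets its tension to zero; the tissue then recoils from
the pre-ablation equilibrium under overdamped dynamics dx/dt = F / drag.
The average recoil velocity v0 -- the separation increase of the two
vertices bounding the ablated element between the frame just before
ablation and the first frame after it, divided by the frame interval -- is
the standard relative measure of the tension the element carried.  Only v0
RATIOS are compared between elements, so the drag coefficient (1 in reduced
units) cancels.

For edges the tracked points are the two endpoint vertices; for lateral
faces they are the midpoints of the face's apical and basal edges, so the
readout is the apico-basal extent of the released region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TissueMesh
from .mechanics import MechanicalParams, energy_and_forces, resolve_tensions

__all__ = [
    "RecoilTrack",
    "ablate_element",
    "simulate_recoil",
    "recoil_velocity",
    "recoil_ratio",
    "central_edge",
    "IntegrationError",
]

ELEMENT_KINDS = ("apical_edge", "basal_edge", "lateral_face")


class IntegrationError(RuntimeError):
    pass


@dataclass
class RecoilTrack:
    """Tracked positions of the two points bounding an ablated element.

    ``times[0]`` is the pre-ablation sample (t = t_ablation = 0); subsequent
    samples are post-ablation frames.
    """

    times: np.ndarray
    pos1: np.ndarray  # (n, 3)
    pos2: np.ndarray  # (n, 3)
    t_ablation: float = 0.0
    frame_window: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pos1 = np.asarray(self.pos1, dtype=float).reshape(-1, 3)
        self.pos2 = np.asarray(self.pos2, dtype=float).reshape(-1, 3)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (len(self.times) == len(self.pos1) == len(self.pos2)):
            raise ValueError("times, pos1, pos2 must have equal length")

    @property
    def separation(self) -> np.ndarray:
        return np.linalg.norm(self.pos2 - self.pos1, axis=1)

    @property
    def v0(self) -> float:
        return recoil_velocity(self)


def _check_element(mesh: TissueMesh, element: int, kind: str) -> None:
    if kind not in ELEMENT_KINDS:
        raise ValueError(f"element_kind must be one of {ELEMENT_KINDS}")
    n = {
        "apical_edge": len(mesh.apical_edges),
        "basal_edge": len(mesh.basal_edges),
        "lateral_face": len(mesh.lateral_faces),
    }[kind]
    if not 0 <= element < n:
        raise KeyError(f"unknown {kind} index {element}")


def ablate_element(
    mesh: TissueMesh, params: MechanicalParams, element: int, kind: str
) -> MechanicalParams:
    """Parameters after ablating one element: its tension (edge Lambda-bar or
    lateral-face T-bar) is set to zero, everything else unchanged."""
    _check_element(mesh, element, kind)
    p = params.copy()
    if kind == "lateral_face":
        p.lateral_overrides[element] = 0.0
    else:
        layer = "apical" if kind == "apical_edge" else "basal"
        p.edge_overrides[(layer, element)] = 0.0
    return p


def _track_points(mesh: TissueMesh, X: np.ndarray, element: int, kind: str):
    """The two tracked points (each a set of vertex indices to average)."""
    if kind == "apical_edge":
        e = mesh.apical_edges[element]
        return np.array([e[0]]), np.array([e[1]])
    if kind == "basal_edge":
        e = mesh.basal_edges[element]
        return np.array([e[0]]), np.array([e[1]])
    quad = mesh.lateral_faces[element]  # (a_i, a_j, b_j, b_i)
    return np.array([quad[0], quad[1]]), np.array([quad[2], quad[3]])


def element_length(mesh: TissueMesh, element: int, kind: str) -> float:
    """Current distance between the two tracked points of the element."""
    g1, g2 = _track_points(mesh, mesh.positions, element, kind)
    p1 = mesh.positions[g1].mean(axis=0)
    p2 = mesh.positions[g2].mean(axis=0)
    from .geometry import minimum_image

    return float(np.linalg.norm(minimum_image(p2 - p1, mesh.box)))


def simulate_recoil(
    mesh: TissueMesh,
    params_after: MechanicalParams,
    element: int,
    kind: str,
    drag: float = 1.0,
    dt: float = 2e-5,
    n_frames: int = 8,
    frame_window: float | None = None,
    max_window_search: float = 0.5,
) -> RecoilTrack:
    """Overdamped recoil from the pre-ablation equilibrium.

    Explicit integration of dx/dt = F/drag with ``params_after`` (from
    :func:`ablate_element`).  The two points bounding the element are
    recorded at frame times k * frame_window.  When ``frame_window`` is not
    given it is chosen as the first time at which the separation has grown
    by 1% of the element's pre-ablation length (the in-silico analog of one
    camera frame); pass an explicit common window when comparing elements.

    Raises :class:`IntegrationError` when the energy increases (dt too
    large for stability).
    """
    _check_element(mesh, element, kind)
    resolved = resolve_tensions(mesh, params_after)
    X = mesh.positions.copy()
    g1, g2 = _track_points(mesh, X, element, kind)

    from .geometry import minimum_image

    # frozen unwrap shifts: both tracked point groups in the frame of g1[0]
    ref = X[g1[0]]
    sh1 = minimum_image(X[g1] - ref, mesh.box) - (X[g1] - ref)
    sh2 = minimum_image(X[g2] - ref, mesh.box) - (X[g2] - ref)

    def sep(Xc):
        return float(
            np.linalg.norm((Xc[g2] + sh2).mean(axis=0) - (Xc[g1] + sh1).mean(axis=0))
        )

    sep0 = sep(X)
    L0 = element_length(mesh, element, kind)

    if frame_window is None:
        # probe run: find the 1%-of-length separation time
        Xp = X.copy()
        t = 0.0
        frame_window = max_window_search / n_frames  # fallback: near-zero recoil
        while t < max_window_search:
            _, F = energy_and_forces(mesh, params_after, positions=Xp, resolved=resolved)
            Xp += (dt / drag) * F
            t += dt
            if sep(Xp) - sep0 >= 0.01 * L0:
                frame_window = max(t, 5 * dt)
                break

    n_sub = max(1, int(round(frame_window / dt)))
    h = frame_window / n_sub
    times = [0.0]
    p1s = [(X[g1] + sh1).mean(axis=0)]
    p2s = [(X[g2] + sh2).mean(axis=0)]
    W_prev, _ = energy_and_forces(mesh, params_after, positions=X, resolved=resolved)
    for frame in range(1, n_frames + 1):
        for _ in range(n_sub):
            _, F = energy_and_forces(mesh, params_after, positions=X, resolved=resolved)
            X += (h / drag) * F
        W_now = energy_and_forces(mesh, params_after, positions=X, want_grad=False)[0]
        if not np.isfinite(W_now) or W_now > W_prev + 1e-6 * (1.0 + abs(W_prev)):
            raise IntegrationError(
                f"energy increased during recoil integration at frame {frame}; "
                "use a smaller dt"
            )
        W_prev = W_now
        times.append(frame * frame_window)
        p1s.append((X[g1] + sh1).mean(axis=0))
        p2s.append((X[g2] + sh2).mean(axis=0))

    return RecoilTrack(
        times=np.array(times),
        pos1=np.array(p1s),
        pos2=np.array(p2s),
        frame_window=frame_window,
        meta={
            "element": element,
            "kind": kind,
            "drag": drag,
            "dt": dt,
            "pre_ablation_length": L0,
        },
    )


def recoil_velocity(track: RecoilTrack, window: float | None = None) -> float:
    """Average recoil velocity: separation increase from the sample just
    before ablation to the first sample after it, divided by the frame
    interval (0.25 s for apical/basal edges, 1 s for lateral interfaces in
    the experimental protocol; reduced time here)."""
    t = track.times
    pre = np.nonzero(t <= track.t_ablation)[0]
    post = np.nonzero(t > track.t_ablation)[0]
    if len(pre) == 0:
        raise ValueError("track has no pre-ablation sample")
    if len(post) == 0:
        raise ValueError("track has no post-ablation sample")
    i0, i1 = pre[-1], post[0]
    s = track.separation
    if window is None:
        window = t[i1] - t[i0] if t[i1] > t[i0] else track.frame_window
    return float((s[i1] - s[i0]) / window)


def central_edge(mesh: TissueMesh, layer: str = "apical") -> int:
    """Index of the edge whose midpoint is nearest the box center (an
    interior element away from any stripe boundary in a uniform tissue)."""
    from .geometry import minimum_image

    edges = mesh.apical_edges if layer == "apical" else mesh.basal_edges
    p0 = mesh.positions[edges[:, 0]]
    d = minimum_image(mesh.positions[edges[:, 1]] - p0, mesh.box)
    mid = (p0 + 0.5 * d)[:, :2]
    center = np.array([mesh.box[0] / 2, mesh.box[1] / 2])
    delta = mid - center
    for ax, L in enumerate(mesh.box):
        delta[:, ax] -= L * np.round(delta[:, ax] / L)
    return int(np.argmin((delta**2).sum(axis=1)))


def recoil_ratio(
    mesh: TissueMesh,
    params: MechanicalParams,
    edge: int | None = None,
    n_frames: int = 4,
    dt: float = 2e-5,
) -> dict:
    """Basal/apical recoil-velocity ratio for a matched edge pair.

    Ablates the apical edge ``edge`` and its basal partner (same index) in
    separate runs, using one common frame window (the smaller of the two
    1%-recoil windows) so the comparison is window-consistent.
    """
    if edge is None:
        edge = central_edge(mesh, "apical")
    windows = {}
    for kind in ("apical_edge", "basal_edge"):
        p = ablate_element(mesh, params, edge, kind)
        tr = simulate_recoil(mesh, p, edge, kind, dt=dt, n_frames=1)
        windows[kind] = tr.frame_window
    window = min(windows.values())
    tracks = {}
    v0 = {}
    for kind in ("apical_edge", "basal_edge"):
        p = ablate_element(mesh, params, edge, kind)
        tracks[kind] = simulate_recoil(
            mesh, p, edge, kind, dt=dt, n_frames=n_frames, frame_window=window
        )
        v0[kind] = recoil_velocity(tracks[kind])
    return {
        "edge": edge,
        "frame_window": window,
        "v0_apical": v0["apical_edge"],
        "v0_basal": v0["basal_edge"],
        "ratio": v0["basal_edge"] / v0["apical_edge"],
        "tracks": tracks,
    }
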