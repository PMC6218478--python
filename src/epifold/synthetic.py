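"""Synthetic-data generators emulating the tracked-data structure of the
fold-formation experiments.

Every generator is a pure function of its arguments including the seed, and
targets the analysis interfaces (tracked-vertex tables, recoil tracks,
per-cell time series) rather than images: pixel-level segmentation and
tracking are outside the scope of this package, so fixtures start at the
tracked/segmented level.

* :func:`gen_wedge_cross_section` -- piecewise-linear fold cross sections
  with exactly known geometry (d_a, d_b, l_a, l_b, h_tissue).
* :func:`gen_recoil_track` -- two vertices separating at a constant speed
  after ablation, with optional positional noise.
* :func:`gen_coupled_timeseries` -- per-cell intensity/height series in
  which a relative intensity increase precedes a relative height decrease
  by a configurable delay (mean-reverting log-intensity fluctuations).
* :func:`gen_intensity_table` -- per-cell intensity tables with a known
  fold/neighbor contrast.
"""

from __future__ import annotations

import numpy as np

from .ablation import RecoilTrack
from .fluctuation import CoupledSeries
from .quantify import FOLD_CENTER, NEIGHBOR, CrossSection, SectionCell

__all__ = [
    "gen_wedge_cross_section",
    "gen_recoil_track",
    "gen_coupled_timeseries",
    "gen_intensity_table",
]


def _v_chain(n_seg: int, seg_len: float, depth: float, y_start: float, z0: float):
    """Vertex chain of n_seg segments of length seg_len forming a symmetric
    V of the given signed depth (positive = dip below z0), starting and
    ending at z0.  Returns (n_seg + 1, 2) points."""
    if n_seg < 1:
        raise ValueError("need at least one segment")
    if abs(depth) < 1e-15:
        ys = y_start + seg_len * np.arange(n_seg + 1)
        return np.column_stack([ys, np.full(n_seg + 1, z0)])
    if n_seg < 2:
        raise ValueError("a nonzero depth needs at least 2 fold cells")
    n_half = n_seg // 2
    drop = depth / n_half
    if abs(drop) >= seg_len:
        raise ValueError(
            f"impossible wedge: depth {depth} too large for {n_seg} segments "
            f"of length {seg_len}"
        )
    dy = np.sqrt(seg_len**2 - drop**2)
    zs = [z0]
    ys = [y_start]
    # descend, optional flat middle segment (odd n_seg), ascend
    pattern = [-drop] * n_half + ([0.0] if n_seg % 2 else []) + [drop] * n_half
    seg_dy = [dy] * n_half + ([seg_len] if n_seg % 2 else []) + [dy] * n_half
    for dz, dyy in zip(pattern, seg_dy):
        ys.append(ys[-1] + dyy)
        zs.append(zs[-1] + dz)
    return np.column_stack([ys, zs])


def gen_wedge_cross_section(
    d_a: float,
    d_b: float,
    l_a: float,
    l_b: float,
    h_tissue: float,
    n_neighbor_cells: int = 4,
    n_fold_cells: int = 4,
    seed: int | None = None,
    jitter: float = 0.0,
) -> CrossSection:
    """Deterministic wedge-shaped fold cross section.

    Fold-center cells form a V with apical dip ``d_a`` below the neighbors'
    apical plane and basal extremum ``d_b`` outward (positive = away from
    the apical side); every fold apical segment has length ``l_a`` and every
    basal segment ``l_b``.  ``n_neighbor_cells`` flat neighbors flank each
    side.  ``jitter`` adds seeded Gaussian noise to all vertex coordinates.

    Raises ``ValueError`` for geometrically impossible combinations (e.g.
    d_a >= h_tissue, or a depth too large for the segment count).
    """
    for name, v in (("l_a", l_a), ("l_b", l_b), ("h_tissue", h_tissue)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if n_fold_cells < 1 or n_neighbor_cells < 1:
        raise ValueError("cell counts must be >= 1")
    if h_tissue - d_a + d_b <= 0:
        raise ValueError("impossible wedge: fold-center cells would have "
                         "non-positive height (d_a too large)")

    z_ap, z_ba = h_tissue, 0.0
    ap_chain = _v_chain(n_fold_cells, l_a, d_a, 0.0, z_ap)
    ba_chain = _v_chain(n_fold_cells, l_b, d_b, 0.0, z_ba)
    # center both chains about y = 0
    ap_chain[:, 0] -= ap_chain[-1, 0] / 2.0
    ba_chain[:, 0] -= ba_chain[-1, 0] / 2.0

    # extend each chain with flat neighbor vertices on both sides
    w_n = 0.5 * (l_a + l_b)  # neighbor cell width
    def extend(chain, z0):
        left = [
            [chain[0, 0] - (j + 1) * w_n, z0] for j in range(n_neighbor_cells)
        ][::-1]
        right = [[chain[-1, 0] + (j + 1) * w_n, z0] for j in range(n_neighbor_cells)]
        return np.vstack([left, chain, right])

    ap_all = extend(ap_chain, z_ap)
    ba_all = extend(ba_chain, z_ba)

    if jitter > 0.0:
        # tracking noise perturbs each tracked vertex once; cells sharing a
        # vertex see the same perturbed position
        rng = np.random.default_rng(seed)
        ap_all = ap_all + jitter * rng.standard_normal(ap_all.shape)
        ba_all = ba_all + jitter * rng.standard_normal(ba_all.shape)

    cells: list[SectionCell] = []
    n_cells_total = n_fold_cells + 2 * n_neighbor_cells
    for i in range(n_cells_total):
        # cell i spans chain vertices i..i+1; fold cells sit in the middle
        k = i - n_neighbor_cells
        if 0 <= k < n_fold_cells:
            label, dist = FOLD_CENTER, 0
        else:
            label = NEIGHBOR
            dist = (n_neighbor_cells - i) if k < 0 else (k - n_fold_cells + 1)
        cells.append(
            SectionCell(
                cell_id=i,
                label=label,
                dist=int(dist),
                apical=ap_all[i : i + 2],
                basal=ba_all[i : i + 2],
            )
        )

    pts_a = np.vstack([c.apical for c in cells])
    pts_b = np.vstack([c.basal for c in cells])
    return CrossSection(
        cells=cells,
        apical_outline=pts_a[np.argsort(pts_a[:, 0])],
        basal_outline=pts_b[np.argsort(pts_b[:, 0])],
        axis="x",
        offset=0.0,
    )


def gen_recoil_track(
    v_true: float,
    window: float = 0.25,
    n_frames: int = 8,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sep0: float = 10.0,
) -> RecoilTrack:
    """Two tracked vertices separating at constant speed ``v_true`` after
    ablation at t = 0, sampled every ``window`` with one pre-ablation frame.

    ``noise_sd`` is the per-coordinate positional tracking noise (seeded).
    With zero noise, :func:`epifold.ablation.recoil_velocity` returns
    ``v_true`` exactly.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    times = np.arange(n_frames + 1) * window  # times[0] = 0 is pre-ablation
    half = sep0 / 2.0 + v_true / 2.0 * np.maximum(times, 0.0)
    pos1 = np.column_stack([-half, np.zeros_like(half), np.zeros_like(half)])
    pos2 = np.column_stack([half, np.zeros_like(half), np.zeros_like(half)])
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        pos1 = pos1 + noise_sd * rng.standard_normal(pos1.shape)
        pos2 = pos2 + noise_sd * rng.standard_normal(pos2.shape)
    return RecoilTrack(
        times=times,
        pos1=pos1,
        pos2=pos2,
        frame_window=window,
        meta={"v_true": v_true, "noise_sd": noise_sd, "seed": seed},
    )


def gen_coupled_timeseries(
    n_cells: int = 12,
    duration: float = 600.0,
    dt_sample: float = 10.0,
    delay: float = 22.0,
    coupling: float = 1.0,
    noise_sd: float = 0.004,
    trend: float = 0.0,
    seed: int | None = None,
    fluct_sd: float = 0.2,
    fluct_tau: float = 30.0,
    a0: float = 100.0,
    h0: float = 30.0,
    group: str = "fold",
) -> list[CoupledSeries]:
    """Coupled per-cell intensity/height series with a known delay.

    Log-intensity follows a seeded mean-reverting (Ornstein-Uhlenbeck)
    fluctuation process with stationary s.d. ``fluct_sd`` and correlation
    time ``fluct_tau`` (seconds).  The relative height rate is
    ``-coupling`` times the relative intensity rate delayed by ``delay``,
    plus white noise of rate s.d. ``noise_sd`` (1/s at 1 s resolution) and a
    constant relative ``trend`` (1/s; negative values give the long-term
    height decrease of fold cells).  Both series are strictly positive by
    construction; simulation runs at 1 s resolution, then samples every
    ``dt_sample``.
    """
    if dt_sample <= 0:
        raise ValueError("dt_sample must be > 0")
    if duration < 5 * delay + 5 * dt_sample:
        raise ValueError("duration must be much longer than the delay")
    rng = np.random.default_rng(seed)
    dt_f = 1.0
    n_f = int(round(duration / dt_f)) + 1
    d_idx = int(round(delay / dt_f))
    out = []
    for cid in range(n_cells):
        # exact OU discretization for log-intensity
        rho = np.exp(-dt_f / fluct_tau)
        x = np.empty(n_f)
        x[0] = fluct_sd * rng.standard_normal()
        innov = fluct_sd * np.sqrt(1 - rho**2) * rng.standard_normal(n_f - 1)
        for i in range(1, n_f):
            x[i] = rho * x[i - 1] + innov[i - 1]
        # relative intensity rate on the fine grid (central differences)
        rate_x = np.zeros(n_f)
        rate_x[1:-1] = (x[2:] - x[:-2]) / (2 * dt_f)
        # integrate log-height with the delayed, inverted coupling
        y = np.empty(n_f)
        y[0] = 0.0
        noise = noise_sd * np.sqrt(dt_f) * rng.standard_normal(n_f - 1)
        for i in range(n_f - 1):
            r = rate_x[i - d_idx] if i - d_idx >= 0 else 0.0
            y[i + 1] = y[i] + dt_f * (-coupling * r + trend) + noise[i]
        if np.any(np.abs(x) > 20) or np.any(np.abs(y) > 20):
            raise ValueError("parameters drive the series out of range")
        stride = int(round(dt_sample / dt_f))
        ts = np.arange(0, n_f, stride) * dt_f
        out.append(
            CoupledSeries(
                times=ts,
                a_l=a0 * np.exp(x[::stride]),
                h=h0 * np.exp(y[::stride]),
                cell_id=cid,
                group=group,
            )
        )
    return out


def gen_intensity_table(
    n_fold: int,
    n_neighbor: int,
    contrast: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Per-cell intensity table: neighbors around 1, fold cells around
    ``contrast``, with multiplicative lognormal noise of s.d. parameter
    ``noise_sd`` (mean-one noise, so group means stay at 1 and contrast).

    Returns ``(intensities, labels)`` arrays of length n_fold + n_neighbor.
    """
    if n_fold < 1 or n_neighbor < 1:
        raise ValueError("cell counts must be >= 1")
    if contrast <= 0:
        raise ValueError("contrast must be > 0")
    rng = np.random.default_rng(seed)

    def noisy(mean: float, n: int) -> np.ndarray:
        if noise_sd <= 0:
            return np.full(n, mean)
        return mean * np.exp(noise_sd * rng.standard_normal(n) - noise_sd**2 / 2.0)

    intensities = np.concatenate([noisy(contrast, n_fold), noisy(1.0, n_neighbor)])
    labels = np.array(["fold"] * n_fold + ["neighbor"] * n_neighbor)
    return intensities, labels
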