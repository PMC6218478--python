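"""Cross-correlation of pulsatile F-actin intensity and cell-height changes.

For each cell, two uniformly sampled series are compared: lateral F-actin
intensity a_l(t) (arbitrary fluorescence units) and apico-basal cell height
h(t).  The statistic is the cross-correlation of their *relative rates of
change*,

    C(tau) = < (1/a_l da_l/dt)(t) * (1/h dh/dt)(t + tau) >,

averaged over overlapping times per cell and then (unweighted) over cells.
A negative minimum at positive lag means an intensity increase is followed
by a height decrease after that delay.

Conventions (recorded in output metadata): relative rates use central
differences, g_i = (x_{i+1} - x_{i-1}) / (2 dt x_i), endpoints dropped; the
correlation is the plain product mean (covariance-style, matching the
formula above), with a Pearson-normalized variant behind a flag; series are
not detrended by default -- slow height drift is part of the signal -- with
an optional linear detrend for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoupledSeries",
    "CrossCorrResult",
    "relative_rate",
    "cross_correlation",
    "min_lag",
    "null_bound",
]


@dataclass
class CoupledSeries:
    """Paired per-cell time series of lateral intensity and cell height."""

    times: np.ndarray  # seconds, uniform step
    a_l: np.ndarray  # lateral F-actin intensity, > 0
    h: np.ndarray  # cell height, > 0
    cell_id: int = 0
    group: str = "fold"  # 'fold' | 'neighbor'

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a_l = np.asarray(self.a_l, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if not (len(self.times) == len(self.a_l) == len(self.h)):
            raise ValueError("times, a_l, h must have equal length")
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("sampling must be uniform")
        if np.any(self.a_l <= 0) or np.any(self.h <= 0):
            raise ValueError("a_l and h must be strictly positive")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class CrossCorrResult:
    """C(tau) per cell and cell-averaged, on a symmetric grid of lags."""

    lags: np.ndarray  # seconds, multiples of the sampling step
    C: np.ndarray  # cell-averaged correlation (NaN where missing)
    C_per_cell: np.ndarray  # (n_cells, n_lags)
    n_cells: int
    meta: dict = field(default_factory=dict)


def relative_rate(series: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Relative rate of change (1/x) dx/dt by central differences.

    g_i = (x_{i+1} - x_{i-1}) / (2 dt x_i); the two endpoints are dropped,
    so the result is 2 samples shorter than the input.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("series must have length >= 3")
    if np.any(x <= 0):
        raise ValueError("series must be strictly positive")
    return (x[2:] - x[:-2]) / (2.0 * dt * x[1:-1])


def _xcorr_pair(g1: np.ndarray, g2: np.ndarray, lags_idx: np.ndarray, min_overlap: int):
    """C(k) = mean_t g1(t) g2(t + k) over overlapping samples, per lag."""
    n = len(g1)
    out = np.full(len(lags_idx), np.nan)
    for i, k in enumerate(lags_idx):
        if k >= 0:
            a, b = g1[: n - k], g2[k:]
        else:
            a, b = g1[-k:], g2[: n + k]
        if len(a) >= min_overlap:
            out[i] = float(np.mean(a * b))
    return out


def cross_correlation(
    g1,
    g2,
    max_lag: float,
    dt: float | None = None,
    normalized: bool = False,
    min_overlap: int = 5,
) -> CrossCorrResult:
    """Cross-correlation of paired rate series.

    ``g1``/``g2`` are aligned rate series from one cell (1D) or lists of
    per-cell series; ``max_lag`` is in time units when ``dt`` is given,
    otherwise in samples.  Lags with fewer than ``min_overlap`` overlapping
    samples are reported as missing (NaN).  ``normalized=True`` divides each
    cell's C by the product of the two rate standard deviations.
    """
    if isinstance(g1, np.ndarray) and g1.ndim == 1:
        g1, g2 = [g1], [g2]
    if len(g1) != len(g2):
        raise ValueError("g1 and g2 must hold the same number of cells")
    step = 1.0 if dt is None else float(dt)
    K = int(np.floor(max_lag / step))
    if K < 1:
        raise ValueError("max_lag smaller than one sampling step")
    lags_idx = np.arange(-K, K + 1)
    per_cell = []
    for a, b in zip(g1, g2):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired rate series must be aligned")
        if K >= len(a):
            raise ValueError("max_lag must be smaller than the series span")
        c = _xcorr_pair(a, b, lags_idx, min_overlap)
        if normalized:
            denom = a.std() * b.std()
            c = c / denom if denom > 0 else c * np.nan
        per_cell.append(c)
    per_cell = np.array(per_cell)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lag -> NaN
        avg = np.nanmean(per_cell, axis=0)
    return CrossCorrResult(
        lags=lags_idx * step,
        C=avg,
        C_per_cell=per_cell,
        n_cells=len(per_cell),
        meta={
            "normalized": normalized,
            "min_overlap": min_overlap,
            "estimator": "central-difference relative rates; per-cell product "
            "mean then unweighted cell average",
        },
    )


def min_lag(result: CrossCorrResult) -> tuple[float, float]:
    """Grid argmin of the cell-averaged C; ties broken toward smallest |tau|."""
    C = result.C
    if len(C) == 0 or np.all(np.isnan(C)):
        raise ValueError("empty cross-correlation")
    cmin = np.nanmin(C)
    candidates = np.nonzero(C == cmin)[0]
    best = candidates[np.argmin(np.abs(result.lags[candidates]))]
    return float(result.lags[best]), float(C[best])


def null_bound(g1, g2, max_lag: float, dt: float | None = None, z: float = 3.0) -> float:
    """Null-hypothesis bound on |C(tau)| for independent rate series.

    Bartlett-type variance for the cross-covariance of two independent,
    individually autocorrelated series: Var C(tau) ~ (1/n) sum_k
    gamma_1(k) gamma_2(k), pooled over cells.  For white noise this reduces
    to var_1 var_2 / n.  Returns ``z`` standard deviations.
    """
    if isinstance(g1, np.ndarray) and g1.ndim == 1:
        g1, g2 = [g1], [g2]
    var_sum = 0.0
    n_tot = 0
    for a, b in zip(g1, g2):
        a = np.asarray(a, dtype=float) - np.mean(a)
        b = np.asarray(b, dtype=float) - np.mean(b)
        n = len(a)
        kmax = min(n - 1, 3 * int(np.ceil(max_lag / (dt or 1.0))) + 10)
        s = 0.0
        for k in range(-kmax, kmax + 1):
            ka = abs(k)
            ga = float(np.dot(a[: n - ka], a[ka:]) / n)
            gb = float(np.dot(b[: n - ka], b[ka:]) / n)
            s += ga * gb
        var_sum += s / n
        n_tot += 1
    # cells are independent; the cell average has variance reduced by n_cells
    return z * float(np.sqrt(var_sum / n_tot**2))
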