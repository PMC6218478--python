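"""Numba-compiled inner loops for the vertex-model energy and gradient.

The kernel mirrors the term-by-term definition in :mod:`epifold.mechanics`
(same centroid-fan triangulation for areas and volumes, same degenerate-
element smoothing scales) with explicit loops; it exists purely for speed
and is validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# keep in sync with mechanics.EPS_EDGE / EPS_AREA
EPS_EDGE = 2e-3
EPS_AREA = 1e-3


@njit(cache=True)
def _face_area_grad_into(Q, T, G_local):
    """Fan-triangulated area of loop Q (m,3); gradient times T added to
    G_local (m,3).  Returns the area."""
    m = Q.shape[0]
    cx = cy = cz = 0.0
    for i in range(m):
        cx += Q[i, 0]
        cy += Q[i, 1]
        cz += Q[i, 2]
    cx /= m
    cy /= m
    cz /= m
    area = 0.0
    gcx = gcy = gcz = 0.0
    for i in range(m):
        j = (i + 1) % m
        ax = Q[i, 0] - cx
        ay = Q[i, 1] - cy
        az = Q[i, 2] - cz
        bx = Q[j, 0] - cx
        by = Q[j, 1] - cy
        bz = Q[j, 2] - cz
        nx = ay * bz - az * by
        ny = az * bx - ax * bz
        nz = ax * by - ay * bx
        ln = np.sqrt(nx * nx + ny * ny + nz * nz + EPS_AREA * EPS_AREA)
        area += 0.5 * ln
        hx, hy, hz = nx / ln, ny / ln, nz / ln
        # d|n|/dq for triangle (c, q_i, q_j):
        #   dq_i = nhat x (c - q_j); dq_j = nhat x (q_i - c); dc = nhat x (q_j - q_i)
        ex, ey, ez = cx - Q[j, 0], cy - Q[j, 1], cz - Q[j, 2]
        G_local[i, 0] += 0.5 * T * (hy * ez - hz * ey)
        G_local[i, 1] += 0.5 * T * (hz * ex - hx * ez)
        G_local[i, 2] += 0.5 * T * (hx * ey - hy * ex)
        ex, ey, ez = Q[i, 0] - cx, Q[i, 1] - cy, Q[i, 2] - cz
        G_local[j, 0] += 0.5 * T * (hy * ez - hz * ey)
        G_local[j, 1] += 0.5 * T * (hz * ex - hx * ez)
        G_local[j, 2] += 0.5 * T * (hx * ey - hy * ex)
        ex, ey, ez = Q[j, 0] - Q[i, 0], Q[j, 1] - Q[i, 1], Q[j, 2] - Q[i, 2]
        gcx += 0.5 * (hy * ez - hz * ey)
        gcy += 0.5 * (hz * ex - hx * ez)
        gcz += 0.5 * (hx * ey - hy * ex)
    for i in range(m):
        G_local[i, 0] += T * gcx / m
        G_local[i, 1] += T * gcy / m
        G_local[i, 2] += T * gcz / m
    return area


@njit(cache=True)
def _fan_volume(Q):
    """Signed divergence-theorem contribution of fan-triangulated loop Q."""
    m = Q.shape[0]
    cx = cy = cz = 0.0
    for i in range(m):
        cx += Q[i, 0]
        cy += Q[i, 1]
        cz += Q[i, 2]
    cx /= m
    cy /= m
    cz /= m
    sx = sy = sz = 0.0
    for i in range(m):
        j = (i + 1) % m
        sx += Q[i, 1] * Q[j, 2] - Q[i, 2] * Q[j, 1]
        sy += Q[i, 2] * Q[j, 0] - Q[i, 0] * Q[j, 2]
        sz += Q[i, 0] * Q[j, 1] - Q[i, 1] * Q[j, 0]
    return (cx * sx + cy * sy + cz * sz) / 6.0


@njit(cache=True)
def _fan_volume_grad_into(Q, fac, G_local):
    """Add fac * dV/dQ of the fan-triangulated loop Q into G_local (m,3)."""
    m = Q.shape[0]
    cx = cy = cz = 0.0
    for i in range(m):
        cx += Q[i, 0]
        cy += Q[i, 1]
        cz += Q[i, 2]
    cx /= m
    cy /= m
    cz /= m
    sx = sy = sz = 0.0
    for i in range(m):
        j = (i + 1) % m
        # triangle (c, q_i, q_j): dV/dq_i += (q_j x c)/6 ; dV/dq_j += (c x q_i)/6
        G_local[i, 0] += fac * (Q[j, 1] * cz - Q[j, 2] * cy) / 6.0
        G_local[i, 1] += fac * (Q[j, 2] * cx - Q[j, 0] * cz) / 6.0
        G_local[i, 2] += fac * (Q[j, 0] * cy - Q[j, 1] * cx) / 6.0
        G_local[j, 0] += fac * (cy * Q[i, 2] - cz * Q[i, 1]) / 6.0
        G_local[j, 1] += fac * (cz * Q[i, 0] - cx * Q[i, 2]) / 6.0
        G_local[j, 2] += fac * (cx * Q[i, 1] - cy * Q[i, 0]) / 6.0
        sx += Q[i, 1] * Q[j, 2] - Q[i, 2] * Q[j, 1]
        sy += Q[i, 2] * Q[j, 0] - Q[i, 0] * Q[j, 2]
        sz += Q[i, 0] * Q[j, 1] - Q[i, 1] * Q[j, 0]
    for i in range(m):
        G_local[i, 0] += fac * sx / (6.0 * m)
        G_local[i, 1] += fac * sy / (6.0 * m)
        G_local[i, 2] += fac * sz / (6.0 * m)


@njit(cache=True)
def energy_grad(
    X,
    cycA,
    cycB,
    shiftA,
    shiftB,
    lat,
    shiftL,
    edgesA,
    shiftEa,
    edgesB,
    shiftEb,
    T_a_cell,
    T_b_cell,
    T_lat_face,
    lam_a_edge,
    lam_b_edge,
    V0,
    K_V,
    k_spring,
    anchors,
    n_apical,
):
    """Energy, gradient dW/dx, per-cell volumes, and a 7-component breakdown
    (apical, basal, lateral surface; apical, basal edges; springs; volume)."""
    n = X.shape[0]
    C, m = cycA.shape
    L = lat.shape[0]
    E = edgesA.shape[0]
    G = np.zeros((n, 3))
    V = np.empty(C)
    parts = np.zeros(7)

    QA = np.empty((m, 3))
    QB = np.empty((m, 3))
    gA = np.empty((m, 3))
    gB = np.empty((m, 3))
    quad = np.empty((4, 3))
    gquad = np.empty((4, 3))

    # ---- per-cell terms: apical/basal areas + volumes ----
    for ci in range(C):
        for i in range(m):
            for d in range(3):
                QA[i, d] = X[cycA[ci, i], d] + shiftA[ci, i, d]
                QB[i, d] = X[cycB[ci, i], d] + shiftB[ci, i, d]
                gA[i, d] = 0.0
                gB[i, d] = 0.0
        parts[0] += T_a_cell[ci] * _face_area_grad_into(QA, T_a_cell[ci], gA)
        parts[1] += T_b_cell[ci] * _face_area_grad_into(QB, T_b_cell[ci], gB)

        # volume: apical (+), basal (-), lateral outward loops
        vol = _fan_volume(QA) - _fan_volume(QB)
        for i in range(m):
            j = (i + 1) % m
            for d in range(3):
                quad[0, d] = QA[j, d]
                quad[1, d] = QA[i, d]
                quad[2, d] = QB[i, d]
                quad[3, d] = QB[j, d]
            vol += _fan_volume(quad)
        V[ci] = vol
        dWdV = K_V * (vol - V0[ci]) / V0[ci]
        parts[6] += 0.5 * K_V * (vol - V0[ci]) ** 2 / V0[ci]

        _fan_volume_grad_into(QA, dWdV, gA)
        _fan_volume_grad_into(QB, -dWdV, gB)
        for i in range(m):
            j = (i + 1) % m
            for d in range(3):
                quad[0, d] = QA[j, d]
                quad[1, d] = QA[i, d]
                quad[2, d] = QB[i, d]
                quad[3, d] = QB[j, d]
                gquad[0, d] = 0.0
                gquad[1, d] = 0.0
                gquad[2, d] = 0.0
                gquad[3, d] = 0.0
            _fan_volume_grad_into(quad, dWdV, gquad)
            for d in range(3):
                gA[j, d] += gquad[0, d]
                gA[i, d] += gquad[1, d]
                gB[i, d] += gquad[2, d]
                gB[j, d] += gquad[3, d]

        for i in range(m):
            for d in range(3):
                G[cycA[ci, i], d] += gA[i, d]
                G[cycB[ci, i], d] += gB[i, d]

    # ---- lateral faces ----
    for fi in range(L):
        for i in range(4):
            for d in range(3):
                quad[i, d] = X[lat[fi, i], d] + shiftL[fi, i, d]
                gquad[i, d] = 0.0
        parts[2] += T_lat_face[fi] * _face_area_grad_into(quad, T_lat_face[fi], gquad)
        for i in range(4):
            for d in range(3):
                G[lat[fi, i], d] += gquad[i, d]

    # ---- edges ----
    for ei in range(E):
        i0, i1 = edgesA[ei, 0], edgesA[ei, 1]
        dx = X[i1, 0] - X[i0, 0] + shiftEa[ei, 0]
        dy = X[i1, 1] - X[i0, 1] + shiftEa[ei, 1]
        dz = X[i1, 2] - X[i0, 2] + shiftEa[ei, 2]
        ln = np.sqrt(dx * dx + dy * dy + dz * dz + EPS_EDGE * EPS_EDGE)
        parts[3] += lam_a_edge[ei] * ln
        f = lam_a_edge[ei] / ln
        G[i1, 0] += f * dx
        G[i1, 1] += f * dy
        G[i1, 2] += f * dz
        G[i0, 0] -= f * dx
        G[i0, 1] -= f * dy
        G[i0, 2] -= f * dz
    for ei in range(E):
        i0, i1 = edgesB[ei, 0], edgesB[ei, 1]
        dx = X[i1, 0] - X[i0, 0] + shiftEb[ei, 0]
        dy = X[i1, 1] - X[i0, 1] + shiftEb[ei, 1]
        dz = X[i1, 2] - X[i0, 2] + shiftEb[ei, 2]
        ln = np.sqrt(dx * dx + dy * dy + dz * dz + EPS_EDGE * EPS_EDGE)
        parts[4] += lam_b_edge[ei] * ln
        f = lam_b_edge[ei] / ln
        G[i1, 0] += f * dx
        G[i1, 1] += f * dy
        G[i1, 2] += f * dz
        G[i0, 0] -= f * dx
        G[i0, 1] -= f * dy
        G[i0, 2] -= f * dz

    # ---- ECM springs ----
    if k_spring > 0.0 and anchors.shape[0] == n_apical:
        for bi in range(n_apical):
            vi = n_apical + bi
            dx = X[vi, 0] - anchors[bi, 0]
            dy = X[vi, 1] - anchors[bi, 1]
            dz = X[vi, 2] - anchors[bi, 2]
            parts[5] += 0.5 * k_spring * (dx * dx + dy * dy + dz * dz)
            G[vi, 0] += k_spring * dx
            G[vi, 1] += k_spring * dy
            G[vi, 2] += k_spring * dz

    W = parts.sum()
    return W, G, V, parts
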