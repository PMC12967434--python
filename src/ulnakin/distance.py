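"""Exact minimum distance between triangle surfaces.

Ulnocarpal proximity is the shortest 3-D distance between the ulna and a
carpal bone surface, so the distance here is the true surface-to-surface
(triangle-to-triangle) minimum, not a vertex-to-vertex approximation.

Two routes are provided:

:func:`min_distance`
    The production path: a vertex KD-tree gives an upper bound, rigorous
    per-triangle lower bounds and axis-aligned-box pair distances prune the
    candidate set, and only the surviving triangle pairs are evaluated
    exactly.

:func:`min_distance_bruteforce`
    The exhaustive all-pairs evaluation, kept as the reference/validation
    path.  It shares the exact triangle primitives but no search logic.

Both return the distance together with the closest point on each surface
(the "site pair"), and return 0 for touching or interpenetrating surfaces.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TriangleMesh

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Exact primitives (vectorized over pair arrays)
# ---------------------------------------------------------------------------


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", a, b)


def point_triangle_closest(P: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``T[i]`` to point ``P[i]`` (Eberly regions)."""
    B = T[:, 0]
    E0 = T[:, 1] - B
    E1 = T[:, 2] - B
    D = B - P
    a = _dot(E0, E0)
    b = _dot(E0, E1)
    c = _dot(E1, E1)
    d = _dot(E0, D)
    e = _dot(E1, D)
    det = np.maximum(a * c - b * b, _EPS)
    s = b * e - c * d
    t = b * d - a * e

    a_s = np.maximum(a, _EPS)
    c_s = np.maximum(c, _EPS)
    denom_edge = np.maximum(a - 2 * b + c, _EPS)

    inside = s + t <= det
    # region selectors
    r0 = inside & (s >= 0) & (t >= 0)
    r3 = inside & (s < 0) & (t >= 0)
    r5 = inside & (s >= 0) & (t < 0)
    r4 = inside & (s < 0) & (t < 0)
    out = ~inside
    r2 = out & (s < 0)
    r6 = out & (s >= 0) & (t < 0)
    r1 = out & (s >= 0) & (t >= 0)

    S = np.empty_like(s)
    Tt = np.empty_like(t)

    S[r0] = s[r0] / det[r0]
    Tt[r0] = t[r0] / det[r0]

    # region 3: edge s=0
    S[r3] = 0.0
    Tt[r3] = np.clip(-e[r3] / c_s[r3], 0.0, 1.0)
    # region 5: edge t=0
    Tt[r5] = 0.0
    S[r5] = np.clip(-d[r5] / a_s[r5], 0.0, 1.0)
    # region 4: corner at B
    use_s = d[r4] < 0
    s4 = np.where(use_s, np.clip(-d[r4] / a_s[r4], 0.0, 1.0), 0.0)
    t4 = np.where(use_s, 0.0, np.clip(-e[r4] / c_s[r4], 0.0, 1.0))
    S[r4] = s4
    Tt[r4] = t4
    # region 1: edge s+t=1
    numer = (c + e - b - d)[r1]
    s1 = np.clip(numer / denom_edge[r1], 0.0, 1.0)
    S[r1] = s1
    Tt[r1] = 1.0 - s1
    # region 2
    tmp0 = (b + d)[r2]
    tmp1 = (c + e)[r2]
    on_hyp = tmp1 > tmp0
    s2 = np.where(on_hyp, np.clip((tmp1 - tmp0) / denom_edge[r2], 0.0, 1.0), 0.0)
    t2 = np.where(on_hyp, 1.0 - s2, np.clip(-e[r2] / c_s[r2], 0.0, 1.0))
    S[r2] = s2
    Tt[r2] = t2
    # region 6
    tmp0 = (b + e)[r6]
    tmp1 = (a + d)[r6]
    on_hyp = tmp1 > tmp0
    t6 = np.where(on_hyp, np.clip((tmp1 - tmp0) / denom_edge[r6], 0.0, 1.0), 0.0)
    s6 = np.where(on_hyp, 1.0 - t6, np.clip(-d[r6] / a_s[r6], 0.0, 1.0))
    S[r6] = s6
    Tt[r6] = t6

    return B + S[:, None] * E0 + Tt[:, None] * E1


def segment_segment_closest(
    P1: np.ndarray, Q1: np.ndarray, P2: np.ndarray, Q2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closest points on two segments (vectorized, clamped)."""
    d1 = Q1 - P1
    d2 = Q2 - P2
    r = P1 - P2
    a = _dot(d1, d1)
    e = _dot(d2, d2)
    f = _dot(d2, r)
    c = _dot(d1, r)
    b = _dot(d1, d2)
    denom = a * e - b * b

    a_s = np.maximum(a, _EPS)
    e_s = np.maximum(e, _EPS)

    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.maximum(denom, _EPS), 0.0, 1.0), 0.0)
    t = (b * s + f) / e_s
    t_low = t < 0
    t_high = t > 1
    s = np.where(t_low, np.clip(-c / a_s, 0.0, 1.0), s)
    s = np.where(t_high, np.clip((b - c) / a_s, 0.0, 1.0), s)
    t = np.clip(t, 0.0, 1.0)
    # degenerate segments
    both = (a <= _EPS) & (e <= _EPS)
    s = np.where(both, 0.0, np.where(a <= _EPS, 0.0, s))
    t = np.where(both, 0.0, np.where(a <= _EPS, np.clip(f / e_s, 0.0, 1.0), t))
    return P1 + s[:, None] * d1, P2 + t[:, None] * d2


def _segment_pierces_triangle(P: np.ndarray, Q: np.ndarray, T: np.ndarray) -> np.ndarray:
    """True where segment P->Q crosses the interior of triangle T."""
    A, Bv, C = T[:, 0], T[:, 1], T[:, 2]
    n = np.cross(Bv - A, C - A)
    d = Q - P
    denom = _dot(n, d)
    ok = np.abs(denom) > _EPS
    u = np.where(ok, _dot(n, A - P) / np.where(ok, denom, 1.0), -1.0)
    on_seg = ok & (u >= 0.0) & (u <= 1.0)
    X = P + u[:, None] * d
    # barycentric inside test
    v0 = Bv - A
    v1 = C - A
    v2 = X - A
    d00 = _dot(v0, v0)
    d01 = _dot(v0, v1)
    d11 = _dot(v1, v1)
    d20 = _dot(v2, v0)
    d21 = _dot(v2, v1)
    den = np.maximum(d00 * d11 - d01 * d01, _EPS)
    w1 = (d11 * d20 - d01 * d21) / den
    w2 = (d00 * d21 - d01 * d20) / den
    inside = (w1 >= -1e-12) & (w2 >= -1e-12) & (w1 + w2 <= 1.0 + 1e-12)
    return on_seg & inside


def triangle_pair_distance(TA: np.ndarray, TB: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact distance and closest points for triangle pairs ``(TA[i], TB[i])``.

    Considers all vertex–triangle and edge–edge candidates plus the
    edge-pierces-triangle case (which makes interpenetration exactly 0).
    """
    n = TA.shape[0]
    best = np.full(n, np.inf)
    pa = np.zeros((n, 3))
    pb = np.zeros((n, 3))

    def consider(qa: np.ndarray, qb: np.ndarray) -> None:
        nonlocal best, pa, pb
        d = np.linalg.norm(qa - qb, axis=1)
        better = d < best
        best[better] = d[better]
        pa[better] = qa[better]
        pb[better] = qb[better]

    # vertices of A against triangle B and vice versa
    for k in range(3):
        q = point_triangle_closest(TA[:, k], TB)
        consider(TA[:, k], q)
        q = point_triangle_closest(TB[:, k], TA)
        consider(q, TB[:, k])
    # all 9 edge pairs
    for i in range(3):
        for j in range(3):
            qa, qb = segment_segment_closest(
                TA[:, i], TA[:, (i + 1) % 3], TB[:, j], TB[:, (j + 1) % 3]
            )
            consider(qa, qb)
    # proper crossings -> contact
    pierced = np.zeros(n, dtype=bool)
    for i in range(3):
        pierced |= _segment_pierces_triangle(TA[:, i], TA[:, (i + 1) % 3], TB)
        pierced |= _segment_pierces_triangle(TB[:, i], TB[:, (i + 1) % 3], TA)
    best[pierced] = 0.0
    return best, pa, pb


# ---------------------------------------------------------------------------
# Mesh-level search
# ---------------------------------------------------------------------------


def _canonical_order(a: TriangleMesh, b: TriangleMesh) -> bool:
    """Deterministic argument ordering so min_distance(a,b) == min_distance(b,a)."""
    ka = (a.n_vertices, a.n_faces)
    kb = (b.n_vertices, b.n_faces)
    if ka != kb:
        return ka <= kb
    ba, bb = a.vertices.tobytes(), b.vertices.tobytes()
    return ba <= bb


def min_distance_bruteforce(
    mesh_a: TriangleMesh, mesh_b: TriangleMesh, chunk: int = 200_000
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exhaustive all-triangle-pairs minimum distance (reference path)."""
    if not _canonical_order(mesh_a, mesh_b):
        d, pb, pa = min_distance_bruteforce(mesh_b, mesh_a, chunk)
        return d, pa, pb
    TA = mesh_a.triangles()
    TB = mesh_b.triangles()
    na, nb = TA.shape[0], TB.shape[0]
    ia, ib = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    ia = ia.ravel()
    ib = ib.ravel()
    best = np.inf
    bpa = bpb = np.zeros(3)
    for s in range(0, ia.size, chunk):
        sl = slice(s, s + chunk)
        d, pa, pb = triangle_pair_distance(TA[ia[sl]], TB[ib[sl]])
        k = int(np.argmin(d))
        if d[k] < best:
            best = float(d[k])
            bpa, bpb = pa[k], pb[k]
    return best, bpa, bpb


def _tri_aabbs(T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return T.min(axis=1), T.max(axis=1)


def min_distance(
    mesh_a: TriangleMesh, mesh_b: TriangleMesh
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum surface-to-surface distance and the closest point pair.

    Returns ``(distance_mm, point_on_a, point_on_b)``; 0 when the surfaces
    touch or interpenetrate.  Symmetric in its arguments.
    """
    if mesh_a.n_faces == 0 or mesh_b.n_faces == 0:
        raise ValueError("both meshes must have faces")
    if not _canonical_order(mesh_a, mesh_b):
        d, pb, pa = min_distance(mesh_b, mesh_a)
        return d, pa, pb

    VA, VB = mesh_a.vertices, mesh_b.vertices
    TA, TB = mesh_a.triangles(), mesh_b.triangles()

    # upper bound from the closest vertex pair
    tree_b = cKDTree(VB)
    dva, jb = tree_b.query(VA)
    ka = int(np.argmin(dva))
    ub = float(dva[ka])
    bpa, bpb = VA[ka].copy(), VB[jb[ka]].copy()

    # rigorous lower bound per triangle: centroid-to-nearest-vertex distance
    # minus the triangle's own centroid reach minus the other mesh's largest
    # triangle diameter (any point of a triangle is within its longest edge
    # of every one of its corners)
    def reach(T: np.ndarray) -> np.ndarray:
        cent = T.mean(axis=1)
        return np.linalg.norm(T - cent[:, None, :], axis=2).max(axis=1)

    def diam(T: np.ndarray) -> np.ndarray:
        e = np.stack(
            [T[:, 0] - T[:, 1], T[:, 1] - T[:, 2], T[:, 2] - T[:, 0]], axis=1
        )
        return np.linalg.norm(e, axis=2).max(axis=1)

    reach_a = reach(TA)
    reach_b = reach(TB)
    diam_a = float(diam(TA).max())
    diam_b = float(diam(TB).max())
    cent_a = TA.mean(axis=1)
    cent_b = TB.mean(axis=1)
    da, _ = tree_b.query(cent_a)
    tree_a = cKDTree(VA)
    db, _ = tree_a.query(cent_b)
    cand_a = np.flatnonzero(da - reach_a - diam_b <= ub)
    cand_b = np.flatnonzero(db - reach_b - diam_a <= ub)
    if cand_a.size == 0 or cand_b.size == 0:
        return ub, bpa, bpb

    # pairwise AABB gap pruning among candidates
    lo_a, hi_a = _tri_aabbs(TA[cand_a])
    lo_b, hi_b = _tri_aabbs(TB[cand_b])
    gap = np.maximum(
        lo_a[:, None, :] - hi_b[None, :, :], lo_b[None, :, :] - hi_a[:, None, :]
    )
    np.maximum(gap, 0.0, out=gap)
    box_d = np.linalg.norm(gap, axis=2)
    ii, jj = np.nonzero(box_d <= ub)
    if ii.size:
        d, pa, pb = triangle_pair_distance(TA[cand_a[ii]], TB[cand_b[jj]])
        k = int(np.argmin(d))
        if d[k] < ub:
            ub = float(d[k])
            bpa, bpb = pa[k], pb[k]
    return ub, bpa, bpb
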