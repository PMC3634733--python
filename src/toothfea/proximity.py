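"""Exact point-to-surface distances and first-hit ray casting.

Vectorized geometric kernels used by the contact stage: the classic
closest-point-on-triangle construction (per-region case analysis), a
KD-tree broad phase over triangle centroids that is exact up to a caller
cutoff, and Moller-Trumbore ray/triangle intersection with a cylindrical
broad phase around each ray.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .meshes import SurfaceMesh


def closest_point_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest point to ``p[i]`` on triangle ``(a[i], b[i], c[i])``.

    All inputs are (N, 3); broadcasting pairs each point with one triangle.
    """
    p, a, b, c = np.broadcast_arrays(
        np.asarray(p, float), np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    )
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    def safe(x):
        return np.where(x == 0.0, 1.0, x)

    v_ab = (d1 / safe(d1 - d3))[:, None]
    v_ac = (d2 / safe(d2 - d6))[:, None]
    v_bc = ((d4 - d3) / safe((d4 - d3) + (d5 - d6)))[:, None]
    denom = safe(va + vb + vc)
    v_in = (vb / denom)[:, None]
    w_in = (vc / denom)[:, None]

    conditions = [
        (d1 <= 0) & (d2 <= 0),                       # vertex A
        (d3 >= 0) & (d4 <= d3),                      # vertex B
        (d6 >= 0) & (d5 <= d6),                      # vertex C
        (vc <= 0) & (d1 >= 0) & (d3 <= 0),           # edge AB
        (vb <= 0) & (d2 >= 0) & (d6 <= 0),           # edge AC
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),  # edge BC
    ]
    choices = [
        a,
        b,
        c,
        a + v_ab * ab,
        a + v_ac * ac,
        b + v_bc * (c - b),
    ]
    interior = a + v_in * ab + w_in * ac
    conditions = [cond[:, None] for cond in conditions]
    return np.select(conditions, choices, default=interior)


def point_triangle_distances(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    q = closest_point_on_triangles(p, a, b, c)
    return np.linalg.norm(np.asarray(p, float) - q, axis=-1)


class SurfaceDistance:
    """Point-to-surface distance with a centroid KD-tree broad phase.

    Distances below ``cutoff`` are exact; larger distances are reported as
    a value that is guaranteed to exceed ``cutoff`` (a centroid-based
    upper bound), which is all the contact stage needs.
    """

    def __init__(self, surface: SurfaceMesh):
        self.surface = surface
        self._tri = surface.vertices[surface.triangles]
        self._centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        # max distance from any triangle centroid to its own vertices
        self._r_max = float(
            np.linalg.norm(self._tri - self._centroids[:, None, :], axis=2).max()
        )

    def query(self, points: np.ndarray, cutoff: float | None = None) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d_cent, nearest = self._tree.query(points)
        upper = point_triangle_distances(
            points,
            self._tri[nearest, 0], self._tri[nearest, 1], self._tri[nearest, 2],
        )
        if cutoff is None:
            cutoff = np.inf
        # points whose centroid lower bound already exceeds the cutoff keep
        # their (over-)estimate; the rest are refined exactly
        refine = (d_cent - self._r_max) <= np.minimum(cutoff, upper)
        dist = upper.copy()
        if refine.any():
            idx = np.flatnonzero(refine)
            radius = np.minimum(upper[idx], cutoff + self._r_max) + self._r_max + 1e-12
            neighborhoods = self._tree.query_ball_point(points[idx], r=radius)
            pairs_p = np.concatenate(
                [np.full(len(nb), i) for i, nb in zip(idx, neighborhoods)]
            ).astype(np.int64) if len(idx) else np.empty(0, np.int64)
            pairs_t = (
                np.concatenate([np.asarray(nb, np.int64) for nb in neighborhoods])
                if len(idx) else np.empty(0, np.int64)
            )
            if len(pairs_p):
                d = point_triangle_distances(
                    points[pairs_p],
                    self._tri[pairs_t, 0], self._tri[pairs_t, 1], self._tri[pairs_t, 2],
                )
                np.minimum.at(dist, pairs_p, d)
        return dist


def brute_force_surface_distance(points: np.ndarray, surface: SurfaceMesh) -> np.ndarray:
    """All-pairs exact distance (no spatial index) — the testing oracle."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.vertices[surface.triangles]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        d = point_triangle_distances(
            np.broadcast_to(p, (len(tri), 3)), tri[:, 0], tri[:, 1], tri[:, 2]
        )
        out[i] = d.min()
    return out


def ray_surface_first_hits(
    origins: np.ndarray, direction: np.ndarray, surface: SurfaceMesh
) -> np.ndarray:
    """Smallest non-negative hit parameter per ray (NaN when no hit).

    All rays share one direction (the occlusal approach).  A KD-tree over
    triangle centroids projected onto the plane perpendicular to the ray
    direction provides the candidate set for each ray.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # orthonormal basis of the perpendicular plane
    seed = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    tri = surface.vertices[surface.triangles]
    cent = tri.mean(axis=1)
    proj = np.column_stack([cent @ e1, cent @ e2])
    r_max = float(np.linalg.norm(tri - cent[:, None, :], axis=2).max())
    tree = cKDTree(proj)
    origin_proj = np.column_stack([origins @ e1, origins @ e2])
    neighborhoods = tree.query_ball_point(origin_proj, r=r_max + 1e-9)

    t_hit = np.full(len(origins), np.inf)
    pairs_r = np.concatenate(
        [np.full(len(nb), i) for i, nb in enumerate(neighborhoods)]
    ).astype(np.int64) if len(origins) else np.empty(0, np.int64)
    pairs_t = (
        np.concatenate([np.asarray(nb, np.int64) for nb in neighborhoods])
        if len(origins) else np.empty(0, np.int64)
    )
    if len(pairs_r) == 0:
        return np.where(np.isfinite(t_hit), t_hit, np.nan)
    # Moller-Trumbore
    v0, v1, v2 = tri[pairs_t, 0], tri[pairs_t, 1], tri[pairs_t, 2]
    e_1, e_2 = v1 - v0, v2 - v0
    h = np.cross(np.broadcast_to(d, e_1.shape), e_2)
    det = np.einsum("ij,ij->i", e_1, h)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
    s = origins[pairs_r] - v0
    u = inv * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e_1)
    v = inv * (q @ d)
    t = inv * np.einsum("ij,ij->i", e_2, q)
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t >= -1e-9)
    if hit.any():
        np.minimum.at(t_hit, pairs_r[hit], t[hit])
    return np.where(np.isfinite(t_hit), t_hit, np.nan)
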