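"""Deterministic ray–triangle casting with a bounding-volume hierarchy.

The renderer needs, for every pixel, the nearest ray–triangle hit together
with barycentric coordinates for texture lookup.  Hits at equal distance
(shared edges, coincident surfaces) are broken deterministically toward the
lowest triangle index, so renders are bit-reproducible and a brute-force
scan over all triangles returns the identical answer.

Kernels are numba-compiled; the BVH is a flat-array median-split tree built
once per scene in Python and traversed inside the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

# Hits closer than this along the ray are ignored (self-intersection guard).
T_MIN = 1e-6
# Two hits within this distance (mm) count as a tie -> lowest index wins.
TIE_EPS = 1e-6
_LEAF_SIZE = 4


@njit(cache=True)
def _intersect(ox, oy, oz, dx, dy, dz, v0, e1, e2, tri):
    """Moller-Trumbore for a single ray/triangle; returns (t, u, v) or t=-1."""
    p0x, p0y, p0z = v0[tri, 0], v0[tri, 1], v0[tri, 2]
    e1x, e1y, e1z = e1[tri, 0], e1[tri, 1], e1[tri, 2]
    e2x, e2y, e2z = e2[tri, 0], e2[tri, 1], e2[tri, 2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-12 < det < 1e-12:
        return -1.0, 0.0, 0.0
    inv = 1.0 / det
    tx, ty, tz = ox - p0x, oy - p0y, oz - p0z
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-12 or u > 1.0 + 1e-12:
        return -1.0, 0.0, 0.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return -1.0, 0.0, 0.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t < T_MIN:
        return -1.0, 0.0, 0.0
    return t, u, v


@njit(cache=True)
def _cast_brute(origins, dirs, v0, e1, e2, out_t, out_tri, out_u, out_v):
    n_rays = origins.shape[0]
    n_tri = v0.shape[0]
    for r in range(n_rays):
        best_t = np.inf
        best_tri = -1
        best_u = 0.0
        best_v = 0.0
        ox, oy, oz = origins[r, 0], origins[r, 1], origins[r, 2]
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        for tri in range(n_tri):
            t, u, v = _intersect(ox, oy, oz, dx, dy, dz, v0, e1, e2, tri)
            if t > 0.0 and (t < best_t - TIE_EPS
                            or (abs(t - best_t) <= TIE_EPS and tri < best_tri)):
                best_t, best_tri, best_u, best_v = t, tri, u, v
        out_t[r] = best_t if best_tri >= 0 else -1.0
        out_tri[r] = best_tri
        out_u[r] = best_u
        out_v[r] = best_v


@njit(cache=True)
def _cast_bvh(origins, dirs, v0, e1, e2,
              node_min, node_max, node_left, node_right, node_start, node_count,
              tri_order, out_t, out_tri, out_u, out_v):
    n_rays = origins.shape[0]
    stack = np.empty(128, dtype=np.int64)
    for r in range(n_rays):
        ox, oy, oz = origins[r, 0], origins[r, 1], origins[r, 2]
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        inv_dx = 1.0 / dx if dx != 0.0 else np.inf
        inv_dy = 1.0 / dy if dy != 0.0 else np.inf
        inv_dz = 1.0 / dz if dz != 0.0 else np.inf
        best_t = np.inf
        best_tri = -1
        best_u = 0.0
        best_v = 0.0
        sp = 0
        stack[sp] = 0
        sp += 1
        while sp > 0:
            sp -= 1
            node = stack[sp]
            # slab test against node AABB
            tx1 = (node_min[node, 0] - ox) * inv_dx
            tx2 = (node_max[node, 0] - ox) * inv_dx
            tmin = min(tx1, tx2)
            tmax = max(tx1, tx2)
            ty1 = (node_min[node, 1] - oy) * inv_dy
            ty2 = (node_max[node, 1] - oy) * inv_dy
            tmin = max(tmin, min(ty1, ty2))
            tmax = min(tmax, max(ty1, ty2))
            tz1 = (node_min[node, 2] - oz) * inv_dz
            tz2 = (node_max[node, 2] - oz) * inv_dz
            tmin = max(tmin, min(tz1, tz2))
            tmax = min(tmax, max(tz1, tz2))
            if tmax < max(tmin, 0.0) or tmin > best_t + TIE_EPS:
                continue
            if node_left[node] < 0:  # leaf
                start = node_start[node]
                for k in range(start, start + node_count[node]):
                    tri = tri_order[k]
                    t, u, v = _intersect(ox, oy, oz, dx, dy, dz, v0, e1, e2, tri)
                    if t > 0.0 and (t < best_t - TIE_EPS
                                    or (abs(t - best_t) <= TIE_EPS
                                        and tri < best_tri)):
                        best_t, best_tri, best_u, best_v = t, tri, u, v
            else:
                stack[sp] = node_left[node]
                sp += 1
                stack[sp] = node_right[node]
                sp += 1
        out_t[r] = best_t if best_tri >= 0 else -1.0
        out_tri[r] = best_tri
        out_u[r] = best_u
        out_v[r] = best_v


@dataclass
class RayHits:
    """Nearest-hit result for a batch of rays.

    ``t`` is the ray parameter (distance in mm for unit directions; for the
    renderer's unnormalised pixel rays it equals the eye-space depth
    magnitude).  ``tri`` is the global triangle index, -1 for a miss;
    ``u, v`` are barycentric coordinates of the hit inside the triangle.
    """

    t: np.ndarray
    tri: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def hit(self) -> np.ndarray:
        return self.tri >= 0


class TriangleIndex:
    """Flat-array BVH over a triangle soup.

    ``cast`` returns exactly the same nearest hit as an exhaustive scan over
    all triangles (ties broken toward the lowest triangle index).
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        faces = np.ascontiguousarray(faces, dtype=np.int64)
        if len(faces) == 0:
            raise ValueError("cannot index an empty triangle set")
        self.v0 = np.ascontiguousarray(vertices[faces[:, 0]])
        self.e1 = np.ascontiguousarray(vertices[faces[:, 1]] - self.v0)
        self.e2 = np.ascontiguousarray(vertices[faces[:, 2]] - self.v0)
        self._build()

    def _build(self) -> None:
        n = len(self.v0)
        tri_min = np.minimum(self.v0, np.minimum(self.v0 + self.e1, self.v0 + self.e2))
        tri_max = np.maximum(self.v0, np.maximum(self.v0 + self.e1, self.v0 + self.e2))
        centroids = 0.5 * (tri_min + tri_max)

        node_min: list[np.ndarray] = []
        node_max: list[np.ndarray] = []
        node_left: list[int] = []
        node_right: list[int] = []
        node_start: list[int] = []
        node_count: list[int] = []
        order = np.arange(n)

        def build(lo: int, hi: int) -> int:
            idx = len(node_min)
            tris = order[lo:hi]
            node_min.append(tri_min[tris].min(axis=0))
            node_max.append(tri_max[tris].max(axis=0))
            node_left.append(-1)
            node_right.append(-1)
            node_start.append(lo)
            node_count.append(hi - lo)
            if hi - lo > _LEAF_SIZE:
                cent = centroids[tris]
                axis = int(np.argmax(cent.max(axis=0) - cent.min(axis=0)))
                mid = (hi - lo) // 2
                # argsort (stable) keeps splits deterministic
                order[lo:hi] = tris[np.argsort(cent[:, axis], kind="stable")]
                left = build(lo, lo + mid)
                right = build(lo + mid, hi)
                node_left[idx] = left
                node_right[idx] = right
            return idx

        import sys

        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 10000))
        try:
            build(0, n)
        finally:
            sys.setrecursionlimit(limit)

        self.node_min = np.ascontiguousarray(node_min, dtype=np.float64)
        self.node_max = np.ascontiguousarray(node_max, dtype=np.float64)
        self.node_left = np.asarray(node_left, dtype=np.int64)
        self.node_right = np.asarray(node_right, dtype=np.int64)
        self.node_start = np.asarray(node_start, dtype=np.int64)
        self.node_count = np.asarray(node_count, dtype=np.int64)
        self.tri_order = np.ascontiguousarray(order, dtype=np.int64)

    def cast(self, origins: np.ndarray, dirs: np.ndarray) -> RayHits:
        origins = np.ascontiguousarray(
            np.broadcast_to(np.asarray(origins, np.float64), np.asarray(dirs).shape)
        )
        dirs = np.ascontiguousarray(dirs, dtype=np.float64)
        n = len(dirs)
        t = np.empty(n)
        tri = np.empty(n, dtype=np.int64)
        u = np.empty(n)
        v = np.empty(n)
        _cast_bvh(origins, dirs, self.v0, self.e1, self.e2,
                  self.node_min, self.node_max, self.node_left, self.node_right,
                  self.node_start, self.node_count, self.tri_order, t, tri, u, v)
        return RayHits(t=t, tri=tri, u=u, v=v)

    def cast_brute_force(self, origins: np.ndarray, dirs: np.ndarray) -> RayHits:
        """Exhaustive scan over all triangles (the oracle the BVH must match)."""
        origins = np.ascontiguousarray(
            np.broadcast_to(np.asarray(origins, np.float64), np.asarray(dirs).shape)
        )
        dirs = np.ascontiguousarray(dirs, dtype=np.float64)
        n = len(dirs)
        t = np.empty(n)
        tri = np.empty(n, dtype=np.int64)
        u = np.empty(n)
        v = np.empty(n)
        _cast_brute(origins, dirs, self.v0, self.e1, self.e2, t, tri, u, v)
        return RayHits(t=t, tri=tri, u=u, v=v)
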