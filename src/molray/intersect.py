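"""Analytic ray-primitive intersections and a triangle BVH.

Scalar entry points (`intersect_sphere`, `intersect_cylinder`,
`intersect_mesh`) return ``None`` on a miss, otherwise ``(t, normal, ...)``
with ``t`` the Euclidean hit distance along the unit ray direction.
Vectorized batch versions used by the renderer live alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ray",
    "intersect_sphere",
    "intersect_cylinder",
    "intersect_mesh",
    "MeshBVH",
]

_T_EPS = 1e-6  # self-hit guard
_MT_EPS = 1e-9  # Moller-Trumbore determinant epsilon


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray  # unit length

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length")
        object.__setattr__(self, "direction", d)


def intersect_sphere(ray: Ray, center, radius: float):
    """Smallest root of |o + t d - c|^2 = r^2 with t > eps, or None.

    Returns (t, outward unit normal).
    """
    c = np.asarray(center, dtype=float)
    oc = ray.origin - c
    b = float(oc @ ray.direction)
    disc = b * b - (float(oc @ oc) - radius * radius)
    if disc < 0:
        return None
    s = np.sqrt(disc)
    for t in (-b - s, -b + s):
        if t > _T_EPS:
            hit = ray.origin + t * ray.direction
            return t, (hit - c) / radius
    return None


def intersect_cylinder(ray: Ray, end_a, end_b, radius: float):
    """Finite open cylinder (no caps); hit must project strictly inside [a, b].

    Returns (t, radial unit normal) or None.  A ray parallel to the axis
    misses (open cylinder convention).
    """
    a = np.asarray(end_a, dtype=float)
    b = np.asarray(end_b, dtype=float)
    axis = b - a
    length = float(np.linalg.norm(axis))
    u = axis / length
    o = ray.origin - a
    d = ray.direction
    dp = d - (d @ u) * u
    op = o - (o @ u) * u
    A = float(dp @ dp)
    if A < 1e-14:
        return None
    B = 2.0 * float(op @ dp)
    C = float(op @ op) - radius * radius
    disc = B * B - 4 * A * C
    if disc < 0:
        return None
    s = np.sqrt(disc)
    for t in ((-B - s) / (2 * A), (-B + s) / (2 * A)):
        if t <= _T_EPS:
            continue
        proj = float((o + t * d) @ u)
        if 0.0 < proj < length:
            hit_rad = (o + t * d) - proj * u
            return t, hit_rad / radius
    return None


# -- triangle mesh BVH -------------------------------------------------------


class MeshBVH:
    """Axis-aligned BVH (median split on the widest centroid axis, leaves of
    at most ``leaf_size`` triangles) over a triangle mesh."""

    def __init__(self, mesh, leaf_size: int = 8):
        self.mesh = mesh
        self.leaf_size = leaf_size
        tris = mesh.triangles
        verts = mesh.vertices
        self.v0 = verts[tris[:, 0]]
        e1 = verts[tris[:, 1]] - self.v0
        e2 = verts[tris[:, 2]] - self.v0
        self.e1 = e1
        self.e2 = e2
        n_tri = len(tris)
        tri_lo = np.minimum(np.minimum(verts[tris[:, 0]], verts[tris[:, 1]]), verts[tris[:, 2]])
        tri_hi = np.maximum(np.maximum(verts[tris[:, 0]], verts[tris[:, 1]]), verts[tris[:, 2]])
        centroids = (tri_lo + tri_hi) / 2
        # flat node arrays: bounds, child/leaf bookkeeping
        self.node_lo: list[np.ndarray] = []
        self.node_hi: list[np.ndarray] = []
        self.node_left: list[int] = []  # -1 for leaf
        self.node_right: list[int] = []
        self.node_start: list[int] = []
        self.node_count: list[int] = []
        self.order = np.arange(n_tri)
        if n_tri:
            self._build(0, n_tri, tri_lo, tri_hi, centroids)

    def _build(self, start: int, end: int, tri_lo, tri_hi, centroids) -> int:
        idx = self.order[start:end]
        lo = tri_lo[idx].min(axis=0)
        hi = tri_hi[idx].max(axis=0)
        node = len(self.node_lo)
        self.node_lo.append(lo)
        self.node_hi.append(hi)
        self.node_left.append(-1)
        self.node_right.append(-1)
        self.node_start.append(start)
        self.node_count.append(end - start)
        if end - start <= self.leaf_size:
            return node
        axis = int(np.argmax(hi - lo))
        order_key = np.argsort(centroids[idx, axis], kind="stable")
        self.order[start:end] = idx[order_key]
        mid = (start + end) // 2
        left = self._build(start, mid, tri_lo, tri_hi, centroids)
        right = self._build(mid, end, tri_lo, tri_hi, centroids)
        self.node_left[node] = left
        self.node_right[node] = right
        return node

    def _ray_box(self, origin, inv_dir, lo, hi) -> bool:
        with np.errstate(invalid="ignore"):
            t0 = (lo - origin) * inv_dir
            t1 = (hi - origin) * inv_dir
        tmin = float(np.max(np.minimum(t0, t1)))
        tmax = float(np.min(np.maximum(t0, t1)))
        return tmax >= max(tmin, 0.0)

    def intersect(self, origin: np.ndarray, direction: np.ndarray):
        """Nearest hit: (t, interpolated unit normal, triangle id) or None."""
        if not self.node_lo:
            return None
        origin = np.asarray(origin, dtype=float)
        direction = np.asarray(direction, dtype=float)
        with np.errstate(divide="ignore"):
            inv_dir = 1.0 / direction
        best = None
        stack = [0]
        while stack:
            node = stack.pop()
            if not self._ray_box(origin, inv_dir, self.node_lo[node], self.node_hi[node]):
                continue
            if self.node_left[node] < 0:
                s, c = self.node_start[node], self.node_count[node]
                for tri in self.order[s : s + c]:
                    hit = self._ray_triangle(origin, direction, int(tri))
                    if hit is not None and (best is None or hit[0] < best[0]):
                        best = hit
            else:
                stack.append(self.node_left[node])
                stack.append(self.node_right[node])
        return best

    def _ray_triangle(self, origin, direction, tri: int):
        # Moller-Trumbore with a small determinant epsilon; rays lying in the
        # triangle plane count as misses
        e1, e2, v0 = self.e1[tri], self.e2[tri], self.v0[tri]
        pvec = np.cross(direction, e2)
        det = float(e1 @ pvec)
        if abs(det) < _MT_EPS:
            return None
        inv_det = 1.0 / det
        tvec = origin - v0
        u = float(tvec @ pvec) * inv_det
        if u < -1e-12 or u > 1 + 1e-12:
            return None
        qvec = np.cross(tvec, e1)
        v = float(direction @ qvec) * inv_det
        if v < -1e-12 or u + v > 1 + 1e-12:
            return None
        t = float(e2 @ qvec) * inv_det
        if t <= _T_EPS:
            return None
        tri_idx = self.mesh.triangles[tri]
        n = (
            (1 - u - v) * self.mesh.normals[tri_idx[0]]
            + u * self.mesh.normals[tri_idx[1]]
            + v * self.mesh.normals[tri_idx[2]]
        )
        ln = np.linalg.norm(n)
        if ln == 0:
            n = np.cross(e1, e2)
            ln = np.linalg.norm(n)
            if ln == 0:
                return None
        return t, n / ln, tri


def intersect_mesh(ray: Ray, bvh: MeshBVH):
    """Nearest positive hit against a BVH-indexed mesh: (t, normal, tri id)."""
    return bvh.intersect(ray.origin, ray.direction)
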