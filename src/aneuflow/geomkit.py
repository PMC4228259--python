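"""Low-level geometric queries on triangle meshes.

Vectorized closest-point-on-surface queries and axis-aligned ray-parity
inside tests, built on numpy + scipy KD-trees.  These back the centerline
refinement, surface repair and volume meshing steps.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriSurfaceMesh


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tri[i]`` to ``points[i]`` (paired, vectorized).

    ``points``: (n, 3); ``tri``: (n, 3, 3).  Ericson's region-based algorithm.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex B
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # vertex C
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    v = np.where(np.abs(denom) > 1e-300, d1 / np.where(denom == 0, 1, denom), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    w = np.where(np.abs(denom) > 1e-300, d2 / np.where(denom == 0, 1, denom), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(np.abs(denom) > 1e-300,
                 (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class ClosestPointQuery:
    """Closest point on a triangle surface, via KD-tree candidate triangles."""

    def __init__(self, mesh: TriSurfaceMesh):
        self.mesh = mesh
        self.face_normals = mesh.face_normals()
        self.tri = mesh.vertices[mesh.faces]
        self.centroids = self.tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        # candidate search must cover the largest triangle circumscale
        self.max_r = float(
            np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max()
        )

    def query(self, points: np.ndarray, k: int = 24):
        """Return (closest_points, distances, face_indices)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k, len(self.tri))
        d_cent, cand = self.tree.query(points, k=k)
        d_cent = np.atleast_2d(d_cent)
        cand = np.atleast_2d(cand)
        n = len(points)
        best_d = np.full(n, np.inf)
        best_pt = np.zeros((n, 3))
        best_f = np.zeros(n, dtype=np.int64)
        for col in range(k):
            # prune: centroid farther than best + max triangle radius
            maybe = d_cent[:, col] <= best_d + self.max_r
            if not maybe.any():
                continue
            f = cand[maybe, col]
            cp = closest_point_on_triangles(points[maybe], self.tri[f])
            d = np.linalg.norm(points[maybe] - cp, axis=1)
            idx = np.flatnonzero(maybe)
            better = d < best_d[idx]
            upd = idx[better]
            best_d[upd] = d[better]
            best_pt[upd] = cp[better]
            best_f[upd] = f[better]
        return best_pt, best_d, best_f

    def signed_clearance(self, points: np.ndarray, k: int = 24) -> np.ndarray:
        """Distance to the surface, negated outside the solid.

        The side is judged by the outward normal of the closest face; exact
        for points whose closest feature is a face interior, and adequate
        near edges at the mesh scales used here.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        cp, d, f = self.query(points, k=k)
        outside = np.einsum("ij,ij->i", points - cp, self.face_normals[f]) > 0
        return np.where(outside, -d, d)


class RayColumnsX:
    """Crossing x-coordinates of +x rays through (y, z) columns.

    Triangles are binned on a uniform (y, z) grid; each column tests only
    its bin.  Used for parity (inside/outside) voxelization.
    """

    def __init__(self, mesh: TriSurfaceMesh, bin_size: float | None = None):
        self.tri = mesh.vertices[mesh.faces]
        yz = self.tri[:, :, 1:]
        self.lo = yz.reshape(-1, 2).min(axis=0)
        self.hi = yz.reshape(-1, 2).max(axis=0)
        if bin_size is None:
            # aim for O(10) triangles per bin
            span = max(self.hi.max() - self.lo.min(), 1e-9)
            bin_size = max(span / 64.0, 1e-9)
        self.bin = bin_size
        tmin = np.floor((yz.min(axis=1) - self.lo) / bin_size).astype(int)
        tmax = np.floor((yz.max(axis=1) - self.lo) / bin_size).astype(int)
        self.nb = (
            int(np.floor((self.hi[0] - self.lo[0]) / bin_size)) + 1,
            int(np.floor((self.hi[1] - self.lo[1]) / bin_size)) + 1,
        )
        self.bins: dict[tuple[int, int], list[int]] = {}
        for t in range(len(self.tri)):
            for by in range(tmin[t, 0], tmax[t, 0] + 1):
                for bz in range(tmin[t, 1], tmax[t, 1] + 1):
                    self.bins.setdefault((by, bz), []).append(t)
        self.bins = {k: np.asarray(v) for k, v in self.bins.items()}

    def crossings(self, y: float, z: float) -> np.ndarray:
        """Sorted x-coordinates where the ray (y, z, +x) crosses the surface."""
        by = int(np.floor((y - self.lo[0]) / self.bin))
        bz = int(np.floor((z - self.lo[1]) / self.bin))
        cand = self.bins.get((by, bz))
        if cand is None:
            return np.empty(0)
        tri = self.tri[cand]
        # 2D barycentric point-in-triangle in the (y, z) projection
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        v0 = c[:, 1:] - a[:, 1:]
        v1 = b[:, 1:] - a[:, 1:]
        v2 = np.array([y, z]) - a[:, 1:]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        denom = d00 * d11 - d01 * d01
        ok = np.abs(denom) > 1e-300
        denom = np.where(ok, denom, 1.0)
        u = (d11 * d20 - d01 * d21) / denom
        v = (d00 * d21 - d01 * d20) / denom
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
        if not hit.any():
            return np.empty(0)
        w = 1.0 - u[hit] - v[hit]
        xs = w * a[hit, 0] + v[hit] * b[hit, 0] + u[hit] * c[hit, 0]
        return np.sort(xs)


def interior_voxels(mesh: TriSurfaceMesh, pitch: float,
                    jitter: tuple[float, float] = (1.7e-4, 2.3e-4),
                    node_offset: float = 0.5):
    """Boolean interior occupancy on a voxel grid covering the mesh.

    Returns (inside (i,j,k) bool, origin, shape).  ``node_offset`` 0.5
    samples cell centres, 0.0 lattice nodes.  Columns whose parity is broken
    by a grazing hit are repaired from a jittered re-cast.
    """
    lo = mesh.vertices.min(axis=0) - pitch
    hi = mesh.vertices.max(axis=0) + pitch
    shape = tuple(np.ceil((hi - lo) / pitch).astype(int) + 1)
    xs = lo[0] + (np.arange(shape[0]) + node_offset) * pitch
    rc = RayColumnsX(mesh)
    inside = np.zeros(shape, dtype=bool)
    for j in range(shape[1]):
        y = lo[1] + (j + node_offset) * pitch + jitter[0] * pitch
        for k in range(shape[2]):
            z = lo[2] + (k + node_offset) * pitch + jitter[1] * pitch
            cx = rc.crossings(y, z)
            if len(cx) % 2 != 0:
                cx = rc.crossings(y + 0.37 * jitter[0] * pitch,
                                  z + 0.41 * jitter[1] * pitch)
                if len(cx) % 2 != 0:
                    continue
            for x0, x1 in zip(cx[0::2], cx[1::2]):
                inside[(xs > x0) & (xs < x1), j, k] = True
    return inside, lo, np.asarray(shape)
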