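"""Constrained 2D triangulation of a simple polygon with interior points.

scipy's Delaunay triangulates the convex hull of the points and may omit
edges of a non-convex boundary loop.  Here every loop edge is enforced by
cavity retriangulation: triangles crossed by a missing constraint segment
are removed and the two resulting pseudo-polygons are ear-clipped.
Triangles outside the polygon are discarded at the end.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point, Polygon


class TriangulationError(ValueError):
    pass


def _orient2d(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _ear_clip(chain: list[int], pts: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the simple polygon given by ``chain`` (CCW indices)."""
    poly = list(chain)
    tris = []
    guard = 0
    while len(poly) > 3:
        guard += 1
        if guard > 10000:
            raise TriangulationError("ear clipping failed to terminate")
        n = len(poly)
        clipped = False
        for i in range(n):
            a, b, c = poly[(i - 1) % n], poly[i], poly[(i + 1) % n]
            if _orient2d(pts[a], pts[b], pts[c]) <= 1e-14:
                continue  # reflex or degenerate corner
            ear = True
            for j in poly:
                if j in (a, b, c):
                    continue
                p = pts[j]
                if (
                    _orient2d(pts[a], pts[b], p) >= -1e-14
                    and _orient2d(pts[b], pts[c], p) >= -1e-14
                    and _orient2d(pts[c], pts[a], p) >= -1e-14
                ):
                    ear = False
                    break
            if ear:
                tris.append((a, b, c))
                poly.pop(i)
                clipped = True
                break
        if not clipped:
            raise TriangulationError("no ear found (self-intersecting chain?)")
    tris.append((poly[0], poly[1], poly[2]))
    return tris


def _ensure_ccw(chain: list[int], pts: np.ndarray) -> list[int]:
    area = 0.0
    n = len(chain)
    for i in range(n):
        a, b = pts[chain[i]], pts[chain[(i + 1) % n]]
        area += a[0] * b[1] - b[0] * a[1]
    return chain if area > 0 else chain[::-1]


def _insert_constraint(tris: list[tuple[int, int, int]], pts: np.ndarray,
                       a: int, b: int) -> list[tuple[int, int, int]]:
    """Force edge (a, b) into the triangulation by cavity retriangulation."""
    seg = LineString([pts[a], pts[b]])
    crossed = []
    for t in tris:
        if a in t and b in t:
            return tris  # already present
        tri_poly = Polygon([pts[t[0]], pts[t[1]], pts[t[2]]])
        inter = seg.intersection(tri_poly)
        if inter.is_empty:
            continue
        if inter.geom_type == "LineString" and inter.length > 1e-12:
            # exclude pure edge-touches along the segment endpoints
            mid = inter.interpolate(0.5, normalized=True)
            if tri_poly.buffer(-1e-12).contains(mid) or tri_poly.contains(mid):
                crossed.append(t)
    if not crossed:
        raise TriangulationError(
            "constraint edge crosses no triangles (degenerate input)"
        )
    # cavity vertices split into the two chains left/right of segment a->b
    cav_vertices = set()
    for t in crossed:
        cav_vertices.update(t)
    cav_vertices.discard(a)
    cav_vertices.discard(b)
    left, right = [], []
    for v in cav_vertices:
        s = _orient2d(pts[a], pts[b], pts[v])
        if s > 0:
            left.append(v)
        elif s < 0:
            right.append(v)
        # collinear cavity vertices would make the constraint ambiguous
        else:
            raise TriangulationError("vertex collinear with constraint edge")
    new_tris = [t for t in tris if t not in crossed]
    for side in (left, right):
        if not side:
            continue
        # order the side chain by angle around the segment midpoint: walk by
        # projecting onto the segment direction
        d = pts[b] - pts[a]
        side_sorted = sorted(side, key=lambda v: np.dot(pts[v] - pts[a], d))
        chain = [a] + side_sorted + [b]
        chain = _ensure_ccw(chain, pts)
        new_tris.extend(_ear_clip(chain, pts))
    return new_tris


def triangulate_polygon(loop_uv: np.ndarray, interior_uv: np.ndarray):
    """Triangulate a simple polygon (ordered loop) plus interior points.

    Returns faces as an (m, 3) int array indexing [loop; interior].  Every
    consecutive loop edge is present; all triangles lie inside the polygon.
    """
    n_loop = len(loop_uv)
    pts = np.vstack([loop_uv, interior_uv]) if len(interior_uv) else np.asarray(
        loop_uv, dtype=float
    )
    if n_loop < 3:
        raise TriangulationError("loop too short")
    dela = Delaunay(pts)
    tris = [tuple(map(int, s)) for s in dela.simplices]
    # enforce CCW triangles for the constraint machinery
    fixed = []
    for t in tris:
        if _orient2d(pts[t[0]], pts[t[1]], pts[t[2]]) < 0:
            t = (t[0], t[2], t[1])
        fixed.append(t)
    tris = fixed

    present = set()
    for t in tris:
        for u, v in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            present.add((min(u, v), max(u, v)))
    for i in range(n_loop):
        a, b = i, (i + 1) % n_loop
        if (min(a, b), max(a, b)) not in present:
            tris = _insert_constraint(tris, pts, a, b)
            present = set()
            for t in tris:
                for u, v in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                    present.add((min(u, v), max(u, v)))

    poly = Polygon(loop_uv)
    shrunk = poly.buffer(1e-9)
    area_floor = 1e-12 * poly.area
    keep = []
    for t in tris:
        # collinear boundary runs can yield zero-area slivers along chords
        if abs(_orient2d(pts[t[0]], pts[t[1]], pts[t[2]])) <= area_floor:
            continue
        c = pts[list(t)].mean(axis=0)
        if shrunk.contains(Point(c)):
            keep.append(t)
    if not keep:
        raise TriangulationError("no triangles inside the polygon")
    return np.asarray(keep, dtype=np.int64)
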