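"""Centerline extraction, neck detection and aneurysm morphometry.

Computes the dimensional parameters of a saccular aneurysm — maximum diameter
D, height H and neck diameter N, all in mm — and the three dimensionless
ratios H/N (aspect ratio), D/H and D/N used as rupture-risk morphometrics.

Definitions: H is measured perpendicular to the neck plane, D is the maximum
diameter of sac cross-sections parallel to the neck plane, and N is the
diameter of the circle with the same area as the neck contour's in-plane
projection (a non-circular orifice has no unique diameter otherwise).

The centerline is a maximal-inscribed-sphere path: a medial voxel path
(Dijkstra on the interior, weighted toward high wall clearance) refined by
moving each point within its normal plane to the locally deepest position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .geomkit import ClosestPointQuery, interior_voxels
from .mesh import TriSurfaceMesh

NECK_EXCESS_THRESHOLD = 0.2  # min relative wall bulge that counts as a sac


class CenterlineError(ValueError):
    """Mesh is not tubular or the seeds are invalid."""


class NeckAbsentError(ValueError):
    """Operation requires a neck but none is present."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class Centerline:
    """Ordered lumen centerline with arc length and local inscribed radius."""

    points: np.ndarray
    arc_length: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if not np.all(np.diff(self.arc_length) > 0):
            raise ValueError("arc length must be strictly increasing")
        if np.any(self.radius <= 0):
            raise ValueError("local radius must be positive")

    def resampled(self, spacing: float) -> "Centerline":
        s = np.arange(self.arc_length[0], self.arc_length[-1], spacing)
        s = np.append(s, self.arc_length[-1])
        pts = np.stack(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)],
            axis=1,
        )
        r = np.interp(s, self.arc_length, self.radius)
        return Centerline(pts, s, r)


@dataclass
class NeckContour:
    """Closed neck loop with its best-fit plane (normal points into the sac)."""

    points: np.ndarray
    plane_point: np.ndarray
    plane_normal: np.ndarray
    planarity_residual: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.plane_point = np.asarray(self.plane_point, dtype=float)
        n = np.asarray(self.plane_normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be nonzero")
        self.plane_normal = n / nn
        if len(self.points) < 3:
            raise ValueError("contour needs at least 3 points")

    def plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.plane_normal
        a = np.array([1.0, 0.0, 0.0])
        if abs(n @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a)
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(n, e1)

    def projected_polygon(self) -> Polygon:
        e1, e2 = self.plane_basis()
        rel = self.points - self.plane_point
        return Polygon(np.stack([rel @ e1, rel @ e2], axis=1))

    def equivalent_diameter(self) -> float:
        """Diameter of the area-equivalent circle of the in-plane projection."""
        return float(2.0 * np.sqrt(self.projected_polygon().area / np.pi))


@dataclass
class AneurysmMorphometry:
    """D, H, N (mm) and the dimensionless ratios H/N, D/H, D/N."""

    D: float
    H: float
    N: float
    H_over_N: float
    D_over_H: float
    D_over_N: float

    def __post_init__(self) -> None:
        if min(self.D, self.H, self.N) <= 0:
            raise ValueError("D, H, N must be positive")
        for num, den, ratio, name in (
            (self.H, self.N, self.H_over_N, "H/N"),
            (self.D, self.H, self.D_over_H, "D/H"),
            (self.D, self.N, self.D_over_N, "D/N"),
        ):
            if abs(ratio - num / den) > 0.005:
                raise ValueError(
                    f"stored ratio {name}={ratio} inconsistent with {num}/{den}"
                )

    @classmethod
    def from_dimensions(cls, D: float, H: float, N: float) -> "AneurysmMorphometry":
        return cls(D=D, H=H, N=N, H_over_N=H / N, D_over_H=D / H, D_over_N=D / N)

    def rounded(self) -> dict:
        """Values at the 2-decimal display precision of clinical reports."""
        return {
            "D": round(self.D, 2), "H": round(self.H, 2), "N": round(self.N, 2),
            "H_over_N": round(self.H_over_N, 2),
            "D_over_H": round(self.D_over_H, 2),
            "D_over_N": round(self.D_over_N, 2),
        }

    def to_dict(self) -> dict:
        return {
            "D_mm": self.D, "H_mm": self.H, "N_mm": self.N,
            "H_over_N": self.H_over_N, "D_over_H": self.D_over_H,
            "D_over_N": self.D_over_N,
        }


# ----------------------------------------------------------------------
# section helpers
# ----------------------------------------------------------------------
def section_loops(mesh: TriSurfaceMesh, origin: np.ndarray,
                  normal: np.ndarray) -> list[np.ndarray]:
    """Ordered closed intersection loops of the mesh with a plane."""
    sec = mesh.to_trimesh().section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return []
    loops = []
    for d in sec.discrete:
        pts = np.asarray(d)
        if len(pts) >= 4 and np.allclose(pts[0], pts[-1]):
            loops.append(pts[:-1])
    return loops


def _loop_containing(loops, origin, normal, target):
    """The loop whose in-plane polygon contains ``target``'s projection."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    t2 = np.array([(target - origin) @ e1, (target - origin) @ e2])
    for lp in loops:
        rel = lp - origin
        poly = Polygon(np.stack([rel @ e1, rel @ e2], axis=1))
        if poly.is_valid and poly.contains(Point(t2)):
            return lp
    return None


# ----------------------------------------------------------------------
# centerline
# ----------------------------------------------------------------------
def extract_centerline(
    mesh: TriSurfaceMesh,
    inlet_seed: np.ndarray,
    outlet_seed: np.ndarray,
    pitch: float | None = None,
) -> Centerline:
    """Maximal-inscribed-sphere centerline from inlet to outlet.

    ``pitch`` is the voxel size of the medial path search (default: twice the
    median surface edge length); the subsequent in-plane refinement makes the
    result pitch-independent to well below the mesh resolution.
    """
    inlet_seed = np.asarray(inlet_seed, dtype=float)
    outlet_seed = np.asarray(outlet_seed, dtype=float)
    if pitch is None:
        pitch = 2.0 * float(np.median(mesh.edge_lengths()))

    inside, origin, shape = interior_voxels(mesh, pitch)
    if not inside.any():
        raise CenterlineError("no interior voxels found (degenerate mesh?)")
    dist = ndimage.distance_transform_edt(inside) * pitch

    idx_map = -np.ones(shape, dtype=np.int64)
    vox = np.argwhere(inside)
    idx_map[tuple(vox.T)] = np.arange(len(vox))
    centers = origin + (vox + 0.5) * pitch

    tree = cKDTree(centers)
    _, i_in = tree.query(inlet_seed)
    _, i_out = tree.query(outlet_seed)
    if np.linalg.norm(centers[i_in] - centers[i_out]) < 2 * pitch:
        raise CenterlineError("inlet and outlet seeds map to the same cap")

    graph = _medial_graph(inside, idx_map, dist, vox, pitch)
    dists, pred = dijkstra(
        graph, directed=False, indices=i_in, return_predecessors=True
    )
    if not np.isfinite(dists[i_out]):
        raise CenterlineError("mesh is not tubular: no interior through-path")
    path = [i_out]
    while path[-1] != i_in:
        path.append(pred[path[-1]])
    path = path[::-1]
    pts = centers[np.asarray(path)]

    pts = np.vstack([inlet_seed, pts, outlet_seed])
    pts = _smooth_polyline(pts, passes=3)
    pts = _resample_polyline(pts, pitch)
    cpq = ClosestPointQuery(mesh)
    pts, radius = _refine_medial(cpq, pts)

    # trim the cap neighbourhoods BEFORE smoothing: there the nearest surface
    # is the end cap itself, so the inscribed distance no longer measures the
    # lumen radius, and smoothing would drag good points toward them
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    margin = max(1.5 * float(np.median(radius)), 2.0 * pitch)
    keep = (s > margin) & (s < s[-1] - margin)
    if keep.sum() < 2:
        raise CenterlineError("vessel too short relative to its radius")
    pts = _smooth_polyline(pts[keep], passes=2)
    _, radius, _ = cpq.query(pts)

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    dedup = np.concatenate([[True], np.diff(s) > 1e-9])
    return Centerline(pts[dedup], s[dedup], radius[dedup])


def _medial_graph(inside, idx_map, dist, vox, pitch):
    """Sparse 26-neighbourhood graph weighted toward deep (medial) voxels."""
    n = len(vox)
    rows, cols, data = [], [], []
    eps = 0.1 * pitch
    shifts = [
        (di, dj, dk)
        for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
        if (di, dj, dk) > (0, 0, 0)
    ]
    shape = inside.shape
    for di, dj, dk in shifts:
        src = vox
        dst = vox + np.array([di, dj, dk])
        ok = (
            (dst[:, 0] >= 0) & (dst[:, 0] < shape[0])
            & (dst[:, 1] >= 0) & (dst[:, 1] < shape[1])
            & (dst[:, 2] >= 0) & (dst[:, 2] < shape[2])
        )
        src, dst = src[ok], dst[ok]
        j = idx_map[tuple(dst.T)]
        ok2 = j >= 0
        src, dst, j = src[ok2], dst[ok2], j[ok2]
        i = idx_map[tuple(src.T)]
        length = pitch * np.sqrt(di * di + dj * dj + dk * dk)
        d_avg = 0.5 * (dist[tuple(src.T)] + dist[tuple(dst.T)])
        w = length / (d_avg + eps) ** 2
        rows.append(i)
        cols.append(j)
        data.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def _smooth_polyline(pts: np.ndarray, passes: int = 1) -> np.ndarray:
    pts = pts.copy()
    for _ in range(passes):
        if len(pts) < 3:
            break
        pts[1:-1] = 0.25 * pts[:-2] + 0.5 * pts[1:-1] + 0.25 * pts[2:]
    return pts


def _resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.round(total / spacing)), 2)
    si = np.linspace(0.0, total, n + 1)
    return np.stack([np.interp(si, s, pts[:, k]) for k in range(3)], axis=1)


def _refine_medial(cpq: ClosestPointQuery, pts: np.ndarray, sweeps: int = 3):
    """Move each point to the deepest position in its normal plane.

    Alternating golden-section line searches along two in-plane axes,
    vectorized over all path points.  The wall-clearance profile across a
    tubular lumen is unimodal, so this converges to the maximal-inscribed
    (medial) position.
    """
    pts = pts.copy()
    tangents = np.gradient(pts, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    ref = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    swap = np.abs(np.einsum("ij,ij->i", tangents, ref)) > 0.9
    ref[swap] = [0.0, 1.0, 0.0]
    e1 = np.cross(tangents, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(tangents, e1)

    _, d0, _ = cpq.query(pts)
    span = float(np.median(d0))
    for _ in range(sweeps):
        for axis in (e1, e2):
            pts = _golden_max(cpq, pts, axis, half_range=0.9 * span)
        span *= 0.35
    _, dist, _ = cpq.query(pts)
    return pts, dist


def _golden_max(cpq, pts, axis, half_range, iters=18):
    """Vectorized golden-section maximization of wall clearance on a segment."""
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(len(pts), -half_range)
    b = np.full(len(pts), half_range)

    def f(t):
        # signed clearance: negative outside the lumen, so the search can
        # never prefer escaping through a cap.  The tiny movement penalty
        # keeps points put where clearance is flat (an end cap dominates).
        dd = cpq.signed_clearance(pts + t[:, None] * axis)
        return dd - 1e-3 * np.abs(t)

    for _ in range(iters):
        c = b - phi * (b - a)
        d = a + phi * (b - a)
        left = f(c) > f(d)
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    t = 0.5 * (a + b)
    return pts + t[:, None] * axis


# ----------------------------------------------------------------------
# neck detection
# ----------------------------------------------------------------------
def detect_neck(
    mesh: TriSurfaceMesh,
    centerline: Centerline,
    excess_threshold: float = NECK_EXCESS_THRESHOLD,
) -> NeckContour | None:
    """Find the orifice contour separating the sac from the parent vessel.

    Returns ``None`` (absent) when no wall region bulges beyond
    ``excess_threshold`` of the local lumen radius — the repaired-vessel and
    plain-tube cases.  Assumes at most one sidewall protrusion.

    The contour is the lowest mesh cross-section, in planes perpendicular to
    the sac axis, that still encircles the sac alone; one step further toward
    the parent the section merges with the parent lumen and its perimeter
    jumps.
    """
    dense = centerline.resampled(
        min(0.25 * float(np.median(centerline.radius)),
            centerline.arc_length[-1] / 50)
    )
    tree = cKDTree(dense.points)
    dist, nearest = tree.query(mesh.vertices)
    r_local = dense.radius[nearest]
    excess = dist - r_local
    rel = excess / r_local
    # mask vertices beyond the centerline span (cap rims project onto the
    # trimmed end samples and would masquerade as a bulge)
    s_end = dense.arc_length[-1]
    s_v = dense.arc_length[nearest]
    interior = (s_v > 0) & (s_v < s_end)
    rel = np.where(interior, rel, 0.0)
    excess = np.where(interior, excess, 0.0)
    if rel.max() < excess_threshold:
        return None

    apex = int(np.argmax(excess))
    c = dense.points[nearest[apex]]
    n0 = mesh.vertices[apex] - c
    n0 /= np.linalg.norm(n0)
    p0 = c + r_local[apex] * n0

    edge = float(np.median(mesh.edge_lengths()))
    delta = 0.5 * edge
    t_apex = (mesh.vertices[apex] - p0) @ n0
    ts = np.arange(t_apex - 2 * delta, -2 * delta, -delta)

    # scan from the apex toward the parent; keep sections until the loop
    # merges with the parent lumen (perimeter jump), then take the minimal
    # orifice: the fillet flares the surface outward just above the merge,
    # so the perimeter minimum marks the neck
    collected = []
    prev_perimeter = None
    for t in ts:
        origin = p0 + t * n0
        loops = section_loops(mesh, origin, n0)
        lp = _loop_containing(loops, origin, n0, origin + 1e-9 * n0)
        if lp is None:
            if collected:
                break
            continue
        per = float(np.linalg.norm(np.diff(np.vstack([lp, lp[:1]]), axis=0),
                                   axis=1).sum())
        if prev_perimeter is not None and per > 1.5 * prev_perimeter:
            break
        collected.append((per, t, lp))
        prev_perimeter = per
    if not collected:
        return None
    # neck = minimal orifice below the sac equator; sections near the apex
    # are small too, so anchor the argmin below the widest section.  A
    # hemispherical sac has its equator at the base: take the lowest section.
    t_equator = max(collected, key=lambda c: c[0])[1]
    below = [c for c in collected if c[1] < t_equator]
    if below:
        per_sel, t_sel, loop = min(below, key=lambda c: c[0])
    else:
        per_sel, t_sel, loop = collected[-1]
    t_lowest = min(c[1] for c in collected)
    if t_sel <= t_lowest + 1e-12:
        # the orifice narrows right down to the merge: bisect toward the
        # true tangency, since the sac widens steeply (~sqrt) just above it
        lo, hi = t_sel - delta, t_sel
        for _ in range(6):
            mid = 0.5 * (lo + hi)
            origin = p0 + mid * n0
            loops = section_loops(mesh, origin, n0)
            lp = _loop_containing(loops, origin, n0, origin + 1e-9 * n0)
            if lp is None:
                lo = mid
                continue
            per = float(np.linalg.norm(
                np.diff(np.vstack([lp, lp[:1]]), axis=0), axis=1).sum())
            if per <= 1.3 * per_sel:
                hi, loop = mid, lp
            else:
                lo = mid

    centroid = loop.mean(axis=0)
    rel_pts = loop - centroid
    _, _, vh = np.linalg.svd(rel_pts, full_matrices=False)
    normal = vh[2]
    if normal @ n0 < 0:
        normal = -normal
    residual = float(np.sqrt(np.mean((rel_pts @ normal) ** 2)))
    return NeckContour(
        points=loop, plane_point=centroid, plane_normal=normal,
        planarity_residual=residual,
    )


# ----------------------------------------------------------------------
# morphometry
# ----------------------------------------------------------------------
def compute_morphometry(mesh: TriSurfaceMesh, neck: NeckContour | None,
                        ) -> AneurysmMorphometry:
    """D, H, N and ratios of the sac bounded by ``neck``.

    H is the maximum distance of the sac surface from the neck plane; D the
    maximum diameter over sac cross-sections parallel to the neck plane; N
    the area-equivalent diameter of the neck contour.
    """
    if neck is None:
        raise NeckAbsentError("no neck contour: mesh has no aneurysm sac")
    n = neck.plane_normal
    p = neck.plane_point
    height = (mesh.vertices - p) @ n
    if height.max() <= 0:
        raise NeckAbsentError("no surface on the sac side of the neck plane")
    H = float(height.max())

    edge = float(np.median(mesh.edge_lengths()))
    step = max(0.5 * edge, H / 200.0)
    D = _max_parallel_diameter(mesh, p, n, H, step)
    N = neck.equivalent_diameter()
    return AneurysmMorphometry.from_dimensions(D=D, H=H, N=N)


def _max_parallel_diameter(mesh, p, n, H, step) -> float:
    from scipy.spatial import ConvexHull

    best = 0.0
    for t in np.arange(0.5 * step, H, step):
        origin = p + t * n
        loops = section_loops(mesh, origin, n)
        lp = _loop_containing(loops, origin, n, origin)
        if lp is None:
            continue
        pts = lp
        if len(pts) > 12:
            try:
                rel = pts - pts.mean(axis=0)
                # project to the plane for a 2D hull
                e1 = np.cross(n, [0.0, 1.0, 0.0])
                if np.linalg.norm(e1) < 1e-6:
                    e1 = np.cross(n, [1.0, 0.0, 0.0])
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(n, e1)
                uv = np.stack([rel @ e1, rel @ e2], axis=1)
                hull = ConvexHull(uv)
                pts = pts[hull.vertices]
            except Exception:
                pass
        d = pts[:, None, :] - pts[None, :, :]
        best = max(best, float(np.sqrt((d**2).sum(axis=2)).max()))
    return best
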