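"""Virtual sac removal and curvature-continuous hole filling.

Recovers the "pre-aneurysm" parent artery: the sac is excised along the neck
plane and the resulting hole is filled with a triangle patch whose curvature
continues the surrounding vessel wall.  The patch is built in three stages:

1. a planar Delaunay triangulation of the boundary loop at the local edge
   length;
2. a thin-plate (discrete biharmonic) solve over the patch with the boundary
   and ``ring_depth`` rings of surrounding vertices as context, giving a
   smooth C1-ish continuation;
3. fixed-order normal-offset sweeps that minimize the variance of the
   discrete (cotangent-weight) mean curvature across patch + context rings,
   driving the patch toward the constant-curvature continuation of the
   parent wall (a cylinder hole refills as a cylinder, a spherical cap as a
   sphere, a flat hole stays flat).

Only patch vertices move; the surrounding vessel is never edited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from shapely.geometry import Point, Polygon

from .cdt import TriangulationError, triangulate_polygon
from .mesh import MeshTopologyError, TriSurfaceMesh
from .morphometry import NeckContour

MAX_SWEEPS = 150
MOVE_TOL = 1e-6  # mm; max vertex move considered converged


class ExcisionError(ValueError):
    """The contour does not separate a sac from the mesh."""


class HoleFillError(ValueError):
    """Hole filling failed (bad loop or degenerate triangulation)."""


@dataclass
class ExcisionResult:
    """Open mesh after sac removal plus the new boundary loop."""

    open_mesh: TriSurfaceMesh
    boundary_loop: np.ndarray  # ordered vertex indices into open_mesh
    removed_face_count: int


# ----------------------------------------------------------------------
# excision
# ----------------------------------------------------------------------
def excise_sac(mesh: TriSurfaceMesh, neck: NeckContour) -> ExcisionResult:
    """Remove all faces on the sac side of the neck plane.

    Faces crossing the plane are re-triangulated so the new boundary lies
    exactly on the plane.  Removal is restricted to the connected component
    of above-plane faces with the tallest protrusion, so a slightly tilted
    neck plane cannot clip the parent wall elsewhere.  The removed-face
    count uses the "any vertex strictly above the plane" rule.
    """
    p = neck.plane_point
    n = neck.plane_normal
    h = (mesh.vertices - p) @ n
    # classify VERTICES: the sac is the connected component of above-plane
    # vertices containing the tallest protrusion near the contour.  Faces
    # are then treated purely from their vertices' classes, so the cut is
    # conforming even when a slightly tilted plane grazes the parent wall
    # elsewhere (those vertices form separate components and are ignored).
    above_v = h > 0.0
    if not above_v.any():
        raise ExcisionError("no vertices above the neck plane")
    comp_id = _vertex_components(mesh, above_v)
    r_neck = 0.5 * neck.equivalent_diameter()
    rel = mesh.vertices - p
    lateral = np.linalg.norm(rel - np.outer(rel @ n, n), axis=1)
    near = above_v & (lateral < 4.0 * r_neck)
    if not near.any():
        raise ExcisionError("no faces above the neck plane: nothing to excise")
    apex = int(np.flatnonzero(near)[np.argmax(h[near])])
    sac_above = comp_id == comp_id[apex]
    edge_scale = float(np.median(mesh.edge_lengths()))
    if h[sac_above].max() < 2.0 * edge_scale:
        raise ExcisionError(
            "contour does not bound a protruding sac (nothing rises above "
            "the plane beyond the mesh scale)"
        )
    above_v = sac_above  # classification used by the splitting below
    sac_mask = above_v[mesh.faces].any(axis=1)
    removed_count = int(sac_mask.sum())

    verts = [mesh.vertices.copy()]
    n_orig = len(mesh.vertices)
    next_id = n_orig
    cut_cache: dict[tuple[int, int], int] = {}
    new_pts: list[np.ndarray] = []

    def cut_vertex(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        if key in cut_cache:
            return cut_cache[key]
        ha, hb = h[a], h[b]
        t = ha / (ha - hb)
        pt = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
        new_pts.append(pt)
        cut_cache[key] = next_id
        next_id += 1
        return cut_cache[key]

    new_faces: list[tuple[int, int, int]] = []
    for fi, f in enumerate(mesh.faces):
        if not sac_mask[fi]:
            new_faces.append(tuple(f))
            continue
        ab = above_v[f]
        if ab.all():
            continue  # fully above: drop
        # rotate so the below/on vertices come in a canonical position
        idx = [0, 1, 2]
        while not (ab[idx[0]] and not ab[idx[2]]):
            idx = idx[1:] + idx[:1]
        a, b, c = (int(f[i]) for i in idx)  # a above; c below
        if ab[idx[1]]:  # a, b above; c below -> keep one triangle
            vca = cut_vertex(c, a)
            vbc = cut_vertex(b, c)
            new_faces.append((vca, vbc, c))
        else:  # a above; b, c below -> keep a quad as two triangles
            vab = cut_vertex(a, b)
            vca = cut_vertex(c, a)
            new_faces.append((vab, b, c))
            new_faces.append((vab, c, vca))

    if new_pts:
        verts.append(np.asarray(new_pts))
    all_verts = np.vstack(verts)
    open_mesh = TriSurfaceMesh(all_verts, np.asarray(new_faces, dtype=np.int64))
    loops = open_mesh.boundary_loops()
    loops = [lp for lp in loops if len(lp) >= 3]
    if len(loops) != 1:
        raise ExcisionError(
            f"excision produced {len(loops)} boundary loops, expected exactly 1"
        )
    # drop unreferenced vertices (the removed sac interior)
    open_mesh, remap = _compact(open_mesh)
    loop = remap[loops[0]]
    return ExcisionResult(open_mesh, loop, removed_count)


def _vertex_components(mesh: TriSurfaceMesh, mask: np.ndarray) -> np.ndarray:
    """Connected-component id per vertex over the masked vertex subgraph."""
    import scipy.sparse as _sp
    from scipy.sparse.csgraph import connected_components

    de = mesh.directed_edges()
    keep = mask[de[:, 0]] & mask[de[:, 1]]
    de = de[keep]
    n = len(mesh.vertices)
    g = _sp.coo_matrix(
        (np.ones(len(de)), (de[:, 0], de[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(g, directed=False)
    labels = labels.astype(np.int64)
    labels[~mask] = -1
    return labels


def _compact(mesh: TriSurfaceMesh):
    used = np.unique(mesh.faces)
    remap = -np.ones(len(mesh.vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriSurfaceMesh(mesh.vertices[used], remap[mesh.faces]), remap


# ----------------------------------------------------------------------
# discrete curvature
# ----------------------------------------------------------------------
def cotan_laplacian(verts: np.ndarray, faces: np.ndarray):
    """Cotangent-weight Laplacian (sparse, n x n) and one-ring areas / 3."""
    n = len(verts)
    i_all, j_all, w_all = [], [], []
    areas = np.zeros(n)
    tri = verts[faces]
    fa = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    for k in range(3):
        np.add.at(areas, faces[:, k], fa / 3.0)
    for k in range(3):
        i = faces[:, k]
        j = faces[:, (k + 1) % 3]
        o = faces[:, (k + 2) % 3]
        u = verts[i] - verts[o]
        v = verts[j] - verts[o]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-12)
        cot = np.clip(cot, -20.0, 20.0)  # guard against slivers
        i_all.append(i)
        j_all.append(j)
        w_all.append(0.5 * cot)
    I = np.concatenate(i_all)
    J = np.concatenate(j_all)
    W = np.concatenate(w_all)
    W_sym = np.concatenate([W, W])
    I_sym = np.concatenate([I, J])
    J_sym = np.concatenate([J, I])
    off = sp.coo_matrix((W_sym, (I_sym, J_sym)), shape=(n, n)).tocsr()
    diag = np.asarray(off.sum(axis=1)).ravel()
    L = off - sp.diags(diag)
    return L, areas


def vertex_mean_curvature(verts: np.ndarray, faces: np.ndarray,
                          normals: np.ndarray | None = None):
    """Signed discrete mean curvature per vertex (1/mm; convex > 0)."""
    L, areas = cotan_laplacian(verts, faces)
    Hvec = L @ verts / (2.0 * areas[:, None])
    if normals is None:
        normals = TriSurfaceMesh(verts, faces).vertex_normals()
    # L x points inward for a convex surface with outward normals; the
    # factor makes a sphere of radius R read 1/R
    return -np.einsum("ij,ij->i", Hvec, normals), areas


# ----------------------------------------------------------------------
# hole filling
# ----------------------------------------------------------------------
def fill_hole(open_mesh: TriSurfaceMesh, boundary_loop: np.ndarray,
              ring_depth: int = 3) -> TriSurfaceMesh:
    """Fill the hole bounded by ``boundary_loop`` with curvature continuity.

    ``ring_depth`` rings of surrounding vertices provide the curvature
    context; only new patch vertices are optimized.  Raises
    :class:`HoleFillError` on degenerate loops.
    """
    if ring_depth < 1:
        raise ValueError("ring_depth must be >= 1")
    loop = np.asarray(boundary_loop, dtype=np.int64)
    if len(loop) < 3:
        raise HoleFillError("boundary loop has fewer than 3 vertices")
    loops = {tuple(sorted(lp.tolist())) for lp in open_mesh.boundary_loops()}
    if tuple(sorted(loop.tolist())) not in loops:
        raise HoleFillError("boundary_loop is not an open boundary of the mesh")

    verts = open_mesh.vertices
    lp_pts = verts[loop]
    centroid = lp_pts.mean(axis=0)
    rel = lp_pts - centroid
    _, _, vh = np.linalg.svd(rel, full_matrices=False)
    normal = vh[2]
    e1, e2 = vh[0], vh[1]
    uv_loop = np.stack([rel @ e1, rel @ e2], axis=1)
    poly = Polygon(uv_loop)
    if not poly.is_valid or poly.area <= 0:
        raise HoleFillError("boundary loop projects to a degenerate polygon")

    # interior sampling on a hex grid at the local edge length
    ell = float(np.median(np.linalg.norm(np.diff(
        np.vstack([lp_pts, lp_pts[:1]]), axis=0), axis=1)))
    interior_uv = _hex_points_inside(poly, ell)

    # existing undirected edges between loop vertices: a patch chord that
    # duplicates one would give an edge shared by three faces
    de = open_mesh.directed_edges()
    existing = {(min(a, b), max(a, b)) for a, b in de.tolist()}
    n_loop = len(loop)
    loop_edge = {(min(i, (i + 1) % n_loop), max(i, (i + 1) % n_loop))
                 for i in range(n_loop)}
    for _attempt in range(6):
        try:
            patch_faces_local = triangulate_polygon(uv_loop, interior_uv)
        except TriangulationError as exc:
            raise HoleFillError(f"could not triangulate the hole: {exc}")
        bad_mid = []
        for f in patch_faces_local:
            for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                if u < n_loop and v < n_loop:
                    key = (min(u, v), max(u, v))
                    if key in loop_edge:
                        continue
                    ga, gb = int(loop[u]), int(loop[v])
                    if (min(ga, gb), max(ga, gb)) in existing:
                        pts2d = np.vstack([uv_loop, interior_uv]) \
                            if len(interior_uv) else uv_loop
                        bad_mid.append(0.5 * (pts2d[u] + pts2d[v]))
        if not bad_mid:
            break
        interior_uv = (
            np.vstack([interior_uv, np.asarray(bad_mid)])
            if len(interior_uv) else np.asarray(bad_mid)
        )
    else:
        raise HoleFillError("patch chords keep duplicating existing mesh edges")
    _check_boundary_edges(patch_faces_local, len(loop))

    # drop interior points the triangulation did not use
    used = np.unique(patch_faces_local)
    used_int = used[used >= len(loop)] - len(loop)
    if len(used_int) < len(interior_uv):
        lut = -np.ones(len(loop) + len(interior_uv), dtype=np.int64)
        lut[: len(loop)] = np.arange(len(loop))
        lut[len(loop) + used_int] = len(loop) + np.arange(len(used_int))
        patch_faces_local = lut[patch_faces_local]
        interior_uv = interior_uv[used_int]

    # global indices: loop verts already exist; interior verts are appended
    n0 = len(verts)
    interior_xyz = centroid + interior_uv @ np.stack([e1, e2])
    glob = np.concatenate([loop, n0 + np.arange(len(interior_uv))])
    patch_faces = glob[patch_faces_local]

    all_verts = np.vstack([verts, interior_xyz])
    # orient patch faces to complete the open boundary consistently:
    # a boundary directed edge (a, b) of the open mesh must appear as (b, a)
    # in the patch
    patch_faces = _orient_patch(open_mesh, loop, patch_faces)
    faces = np.vstack([open_mesh.faces, patch_faces])
    mesh = TriSurfaceMesh(all_verts, faces)
    # the filled loop must be gone; other open boundaries (e.g. the outer rim
    # of a test sheet) may legitimately remain
    n_before = len(open_mesh.boundary_loops())
    n_after = len(mesh.boundary_loops())
    if n_after != n_before - 1:
        raise HoleFillError(
            f"patch left {n_after} boundary loops (expected {n_before - 1})"
        )
    try:
        mesh.validate(require_watertight=False)
    except MeshTopologyError as exc:
        raise HoleFillError(f"patched mesh is degenerate: {exc}")

    free = np.zeros(len(all_verts), dtype=bool)
    free[n0:] = True
    region = _region_vertices(mesh, loop, ring_depth, free)
    new_verts = _thin_plate_init(mesh.vertices, mesh.faces, region, free)
    new_verts = _curvature_variance_sweeps(
        new_verts, mesh.faces, region, free, ell
    )
    out = TriSurfaceMesh(new_verts, faces)
    out.validate(require_watertight=(n_after == 0))
    return out


def _hex_points_inside(poly: Polygon, ell: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    dy = ell * np.sqrt(3) / 2.0
    inner = poly.buffer(-0.55 * ell)
    pts = []
    row = 0
    y = miny
    while y <= maxy:
        x0 = minx + (0.5 * ell if row % 2 else 0.0)
        x = x0
        while x <= maxx:
            if inner.contains(Point(x, y)):
                pts.append((x, y))
            x += ell
        y += dy
        row += 1
    return np.asarray(pts).reshape(-1, 2)


def _check_boundary_edges(patch_faces_local: np.ndarray, n_loop: int) -> None:
    need = {(i, (i + 1) % n_loop) for i in range(n_loop)}
    have = set()
    for f in patch_faces_local:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if a < n_loop and b < n_loop:
                have.add((min(a, b), max(a, b)))
    missing = [e for e in need if (min(e), max(e)) not in have]
    if missing:
        raise HoleFillError(
            f"{len(missing)} boundary edges missing from the patch "
            "triangulation (strongly non-convex loop)"
        )


def _orient_patch(open_mesh, loop, patch_faces):
    # directed boundary edges of the open mesh
    de = open_mesh.directed_edges()
    keys = set(map(tuple, de.tolist()))
    a, b = int(loop[0]), int(loop[1])
    # the open mesh holds either (a,b) or (b,a); the patch must hold the other
    want = (b, a) if (a, b) in keys else (a, b)
    for f in patch_faces:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if (u, v) == want:
                return patch_faces
            if (v, u) == want:
                return patch_faces[:, ::-1]
    # fall back: check any loop edge
    loop_set = set(loop.tolist())
    for f in patch_faces:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if u in loop_set and v in loop_set:
                fwd = (v, u) in keys
                return patch_faces if fwd else patch_faces[:, ::-1]
    raise HoleFillError("could not orient the patch against the open boundary")


def _region_vertices(mesh, loop, ring_depth, free) -> np.ndarray:
    """Vertex set: patch + boundary + ``ring_depth`` context rings."""
    adj = mesh.vertex_adjacency()
    region = set(np.flatnonzero(free).tolist()) | set(loop.tolist())
    frontier = set(loop.tolist())
    for _ in range(ring_depth):
        nxt = set()
        for v in frontier:
            nxt.update(adj[v].tolist())
        nxt -= region
        region |= nxt
        frontier = nxt
    return np.asarray(sorted(region), dtype=np.int64)


def _region_faces(faces: np.ndarray, region: np.ndarray) -> np.ndarray:
    n = int(max(faces.max(), region.max())) + 1
    mask = np.zeros(n, dtype=bool)
    mask[region] = True
    return faces[mask[faces].all(axis=1)]


def _thin_plate_init(verts, faces, region, free):
    """Discrete biharmonic solve for patch vertices over the region mesh."""
    rfaces = _region_faces(faces, region)
    sub = np.unique(rfaces)
    local = -np.ones(len(verts), dtype=np.int64)
    local[sub] = np.arange(len(sub))
    L, areas = cotan_laplacian(verts[sub], local[rfaces])
    Minv = sp.diags(1.0 / np.maximum(areas, 1e-12))
    K = (L.T @ Minv @ L).tocsr()
    f_mask = free[sub]
    if not f_mask.any():
        return verts.copy()
    ff = K[f_mask][:, f_mask]
    fc = K[f_mask][:, ~f_mask]
    x = verts[sub]
    rhs = -fc @ x[~f_mask]
    sol = spla.spsolve(ff.tocsc(), rhs)
    out = verts.copy()
    out[sub[f_mask]] = sol
    return out


def _curvature_variance_sweeps(verts, faces, region, free, ell,
                               max_sweeps: int = MAX_SWEEPS,
                               tol: float = MOVE_TOL):
    """Normal-offset relaxation toward uniform mean curvature.

    Deterministic fixed-order sweeps; each moves every free vertex along its
    normal by a step proportional to its curvature deviation from the
    context-ring average.  Stops at ``tol`` max move or ``max_sweeps``.
    """
    rfaces = _region_faces(faces, region)
    sub = np.unique(rfaces)
    local = -np.ones(len(verts), dtype=np.int64)
    local[sub] = np.arange(len(sub))
    lfaces = local[rfaces]
    f_mask = free[sub]
    context = ~f_mask
    # region border vertices have broken one-rings; their curvature is
    # meaningless, so both target and objective use interior vertices only
    ok = _interior_vertices(lfaces, len(sub))
    ctx = context & ok
    if not ctx.any():
        ctx = context
    out = verts.copy()
    step = 0.05 * ell * ell
    best = out[sub].copy()
    best_var = np.inf
    stall = 0
    for _ in range(max_sweeps):
        x = out[sub]
        mesh_region = TriSurfaceMesh(x, lfaces)
        normals = mesh_region.vertex_normals()
        hcurv, areas = vertex_mean_curvature(x, lfaces, normals)
        h_star = float(np.average(hcurv[ctx], weights=areas[ctx]))
        var = float(np.average((hcurv[ok] - h_star) ** 2, weights=areas[ok]))
        if var < best_var - 1e-16:
            best_var = var
            best = x.copy()
            stall = 0
        else:
            # the explicit flow amplifies high-frequency modes eventually;
            # keep the best iterate and stop once improvement stalls
            stall += 1
            if stall >= 5:
                break
        dx = np.clip(step * (hcurv - h_star), -0.1 * ell, 0.1 * ell)
        move = dx[f_mask]
        x_new = x.copy()
        x_new[f_mask] += move[:, None] * normals[f_mask]
        out[sub] = x_new
        if np.abs(move).max() < tol:
            best = x_new
            break
    out[sub] = best
    return out


def _interior_vertices(faces: np.ndarray, n: int) -> np.ndarray:
    """Vertices whose one-ring is closed (no boundary edge)."""
    m = TriSurfaceMesh(np.zeros((n, 3)), faces)
    de = m.directed_edges()
    keys = de[:, 0] * n + de[:, 1]
    rev = de[:, 1] * n + de[:, 0]
    boundary_edges = de[~np.isin(keys, rev)]
    interior = np.ones(n, dtype=bool)
    interior[boundary_edges.ravel()] = False
    return interior


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------
def grow_hole(open_mesh: TriSurfaceMesh, loop: np.ndarray,
              rings: int) -> tuple[TriSurfaceMesh, np.ndarray]:
    """Enlarge a hole by removing ``rings`` rings of faces around its loop.

    The neck contour sits on the flared junction between sac and parent
    wall; widening the hole past the flare lets the patch continue the
    clean parent surface instead of the junction bulge.
    """
    if rings <= 0:
        return open_mesh, loop
    adj = open_mesh.vertex_adjacency()
    zone = set(loop.tolist())
    frontier = set(loop.tolist())
    for _ in range(rings):
        nxt = set()
        for v in frontier:
            nxt.update(adj[v].tolist())
        nxt -= zone
        zone |= nxt
        frontier = nxt
    zone_arr = np.zeros(len(open_mesh.vertices), dtype=bool)
    zone_arr[list(zone)] = True
    keep = ~zone_arr[open_mesh.faces].any(axis=1)
    trimmed = TriSurfaceMesh(open_mesh.vertices, open_mesh.faces[keep])
    trimmed, remap = _compact(trimmed)
    loops = [lp for lp in trimmed.boundary_loops() if len(lp) >= 3]
    if len(loops) != 1:
        raise ExcisionError(
            f"hole growth produced {len(loops)} boundary loops, expected 1"
        )
    return trimmed, loops[0]


def repair_vessel(mesh: TriSurfaceMesh, neck: NeckContour | None,
                  ring_depth: int = 3, grow_rings: int = 2) -> TriSurfaceMesh:
    """Excise the sac at the neck and fill the hole (identity if no neck).

    ``grow_rings`` widens the excision past the sac-parent junction flare
    before filling, so the patch lands on clean parent wall.
    """
    if neck is None:
        return mesh.copy()
    exc = excise_sac(mesh, neck)
    open_mesh, loop = grow_hole(exc.open_mesh, exc.boundary_loop, grow_rings)
    repaired = fill_hole(open_mesh, loop, ring_depth=ring_depth)
    repaired.validate()
    return repaired
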