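"""Sac excision and curvature-continuous hole filling."""

import numpy as np
import pytest
import trimesh

from aneuflow.geomkit import ClosestPointQuery
from aneuflow.mesh import TriSurfaceMesh
from aneuflow.morphometry import NeckContour, detect_neck, extract_centerline
from aneuflow.repair import (ExcisionError, excise_sac, fill_hole,
                             repair_vessel, vertex_mean_curvature)
from aneuflow.synthetic import generate_vessel


def _compact(V, F):
    used = np.unique(F)
    remap = -np.ones(len(V), dtype=int)
    remap[used] = np.arange(len(used))
    return TriSurfaceMesh(V[used], remap[F])


@pytest.fixture(scope="module")
def sheet_with_hole():
    n, size, hole_r = 40, 20.0, 3.0
    xs = np.linspace(-size / 2, size / 2, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    V = np.stack([X.ravel(), Y.ravel(), np.zeros(n * n)], axis=1)
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b = i * n + j, (i + 1) * n + j
            c, d = (i + 1) * n + j + 1, i * n + j + 1
            F += [(a, b, c), (a, c, d)]
    F = np.asarray(F)
    keep = np.linalg.norm(V[F].mean(axis=1)[:, :2], axis=1) > hole_r
    return _compact(V, F[keep])


@pytest.fixture(scope="module")
def cylinder_with_hole():
    R, L, n_th, n_x = 10.0, 40.0, 72, 40
    th = np.linspace(0, 2 * np.pi, n_th, endpoint=False)
    xs = np.linspace(-L / 2, L / 2, n_x)
    V = np.array([(x, R * np.cos(t), R * np.sin(t)) for x in xs for t in th])
    F = []
    for i in range(n_x - 1):
        for j in range(n_th):
            j2 = (j + 1) % n_th
            a, b = i * n_th + j, (i + 1) * n_th + j
            c, d = (i + 1) * n_th + j2, i * n_th + j2
            F += [(a, b, c), (a, c, d)]
    F = np.asarray(F)
    cent = V[F].mean(axis=1)
    arc = R * (np.arctan2(cent[:, 2], cent[:, 1]) - np.pi / 2)
    inside = (cent[:, 0] / 4.0) ** 2 + (arc / 2.5) ** 2 < 1.0
    return _compact(V, F[~inside]), R


@pytest.fixture(scope="module")
def sphere_with_cap():
    s = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    V, F = np.asarray(s.vertices), np.asarray(s.faces)
    keep = V[F].mean(axis=1)[:, 2] < 7.0
    return _compact(V, F[keep]), 10.0


# ----------------------------------------------------------------------
# fill_hole on analytic surfaces
# ----------------------------------------------------------------------
def test_flat_hole_fills_flat(sheet_with_hole):
    hole = min(sheet_with_hole.boundary_loops(), key=len)
    filled = fill_hole(sheet_with_hole, hole, ring_depth=3)
    new = filled.vertices[len(sheet_with_hole.vertices):]
    assert np.abs(new[:, 2]).max() < 1e-9
    h, _ = vertex_mean_curvature(filled.vertices, filled.faces)
    assert np.abs(h[len(sheet_with_hole.vertices):]).max() < 1e-3


def test_cylinder_hole_recovers_cylinder(cylinder_with_hole):
    cyl, R = cylinder_with_hole
    hole = min(cyl.boundary_loops(), key=len)
    filled = fill_hole(cyl, hole, ring_depth=3)
    new = filled.vertices[len(cyl.vertices):]
    rms = np.sqrt(np.mean((np.linalg.norm(new[:, 1:], axis=1) - R) ** 2))
    assert rms < 0.02 * R


def test_sphere_cap_recovers_sphere(sphere_with_cap):
    sph, R = sphere_with_cap
    hole = sph.boundary_loops()[0]
    filled = fill_hole(sph, hole, ring_depth=3)
    new = filled.vertices[len(sph.vertices):]
    rms = np.sqrt(np.mean((np.linalg.norm(new, axis=1) - R) ** 2))
    assert rms < 0.02 * R
    assert filled.is_watertight()


def test_patch_curvature_continues_context(cylinder_with_hole):
    cyl, R = cylinder_with_hole
    hole = min(cyl.boundary_loops(), key=len)
    filled = fill_hole(cyl, hole, ring_depth=3)
    n0 = len(cyl.vertices)
    h, areas = vertex_mean_curvature(filled.vertices, filled.faces)
    patch = np.arange(n0, len(filled.vertices))
    loop_set = set(hole.tolist())
    adj = filled.vertex_adjacency()
    ring1 = set()
    for v in loop_set:
        ring1.update(adj[v].tolist())
    ring1 -= loop_set | set(patch.tolist())
    ring1 = np.asarray(sorted(ring1))
    h_patch = np.average(h[patch], weights=areas[patch])
    h_ctx = np.average(h[ring1], weights=areas[ring1])
    assert abs(h_patch - h_ctx) < 0.2 * abs(h_ctx)


def test_patch_triangle_size_matches_boundary(cylinder_with_hole):
    cyl, _ = cylinder_with_hole
    hole = min(cyl.boundary_loops(), key=len)
    filled = fill_hole(cyl, hole, ring_depth=3)
    lp = cyl.vertices[hole]
    ell = np.median(np.linalg.norm(np.diff(np.vstack([lp, lp[:1]]), axis=0),
                                   axis=1))
    patch_faces = filled.faces[len(cyl.faces):]
    tri = filled.vertices[patch_faces]
    edges = np.linalg.norm(
        tri[:, [0, 1, 2]] - tri[:, [1, 2, 0]], axis=2)
    assert edges.max() < 2.0 * ell


def test_bad_ring_depth_rejected(sheet_with_hole):
    hole = min(sheet_with_hole.boundary_loops(), key=len)
    with pytest.raises(ValueError):
        fill_hole(sheet_with_hole, hole, ring_depth=0)


# ----------------------------------------------------------------------
# excision
# ----------------------------------------------------------------------
def test_excision_face_count_matches_generator_labels(sac_vessel):
    spec, mesh, truth = sac_vessel
    neck_true = NeckContour(points=truth.neck_contour,
                            plane_point=truth.neck_center,
                            plane_normal=truth.neck_normal,
                            planarity_residual=0.0)
    exc = excise_sac(mesh, neck_true)
    assert exc.removed_face_count == int(truth.sac_face_mask.sum())
    # exactly one boundary loop, lying on the excision plane
    loops = exc.open_mesh.boundary_loops()
    assert len(loops) == 1
    h = (exc.open_mesh.vertices[loops[0]] - truth.neck_center) \
        @ truth.neck_normal
    assert np.abs(h).max() < 1e-9


def test_excising_without_separating_sac_raises(straight_tube):
    _, mesh, truth = straight_tube
    # a plane floating above the tube: nothing to excise
    fake = NeckContour(
        points=np.array([[10.0, 0.0, 5.0], [11.0, 0.0, 5.0],
                         [10.5, 1.0, 5.0]]),
        plane_point=np.array([10.0, 0.0, 5.0]),
        plane_normal=np.array([0.0, 0.0, 1.0]),
        planarity_residual=0.0,
    )
    with pytest.raises(ExcisionError):
        excise_sac(mesh, fake)


# ----------------------------------------------------------------------
# repair_vessel composition
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def repaired_vessel(sac_vessel_measured):
    spec, mesh, truth, cl, neck = sac_vessel_measured
    return repair_vessel(mesh, neck)


def test_repair_recovers_sacfree_twin(sac_vessel, sac_vessel_measured,
                                      repaired_vessel):
    spec, mesh, truth = sac_vessel
    twin, _ = generate_vessel(spec.without_sac())
    rep = repaired_vessel
    q1, q2 = ClosestPointQuery(twin), ClosestPointQuery(rep)
    _, d1, _ = q1.query(rep.vertices)
    _, d2, _ = q2.query(twin.vertices)
    rms = np.sqrt((np.sum(d1**2) + np.sum(d2**2)) / (len(d1) + len(d2)))
    assert rms < 0.05 * spec.parent_radius


def test_repair_preserves_watertightness_and_removes_volume(
        sac_vessel, repaired_vessel):
    _, mesh, _ = sac_vessel
    assert repaired_vessel.is_watertight()
    assert repaired_vessel.volume() < mesh.volume()


def test_repaired_vessel_has_no_neck(sac_vessel, repaired_vessel):
    _, _, truth = sac_vessel
    cl = extract_centerline(repaired_vessel, truth.inlet_center,
                            truth.outlet_center)
    assert detect_neck(repaired_vessel, cl) is None


def test_repair_without_neck_is_identity(straight_tube):
    _, mesh, _ = straight_tube
    out = repair_vessel(mesh, None)
    assert np.array_equal(out.vertices, mesh.vertices)
    assert np.array_equal(out.faces, mesh.faces)


def test_reexcising_repaired_mesh_fails(sac_vessel_measured, repaired_vessel):
    _, _, _, _, neck = sac_vessel_measured
    with pytest.raises(ExcisionError):
        excise_sac(repaired_vessel, neck)


def test_repair_converges_with_resolution(sac_vessel):
    import dataclasses
    spec_c, _, _ = sac_vessel
    rms = []
    for edge in (0.5, 0.25):
        spec = dataclasses.replace(spec_c, mesh_edge_target=edge)
        mesh, truth = generate_vessel(spec)
        twin, _ = generate_vessel(spec.without_sac())
        cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
        rep = repair_vessel(mesh, detect_neck(mesh, cl))
        q = ClosestPointQuery(twin)
        _, d, _ = q.query(rep.vertices)
        rms.append(float(np.sqrt(np.mean(d**2))))
    assert rms[1] < rms[0]
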