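"""Centerline, neck detection and D/H/N morphometry."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from aneuflow.morphometry import (AneurysmMorphometry, NeckAbsentError,
                                  compute_morphometry, detect_neck,
                                  extract_centerline)
from aneuflow.synthetic import SyntheticVesselSpec, generate_vessel


# ----------------------------------------------------------------------
# centerline
# ----------------------------------------------------------------------
def test_cylinder_centerline_is_axis_with_accurate_radius(straight_tube):
    spec, mesh, truth = straight_tube
    cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
    dev = np.linalg.norm(cl.points[:, 1:], axis=1)
    assert dev.max() < 0.1  # mm, on a 2 mm-radius tube
    rel_err = np.abs(cl.radius - spec.parent_radius) / spec.parent_radius
    assert rel_err.max() < 0.01
    assert np.all(np.diff(cl.arc_length) > 0)


def test_curved_tube_centerline_follows_generating_curve():
    spec = SyntheticVesselSpec(parent_radius=2.0, centerline_curvature=0.05,
                               sac_radius=0.0, neck_radius=0.0,
                               mesh_edge_target=0.35, seed=3)
    mesh, truth = generate_vessel(spec)
    cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
    d, _ = cKDTree(truth.centerline_points).query(cl.points)
    assert d.max() < spec.mesh_edge_target


def test_sac_leaves_parent_centerline_unaffected(sac_vessel_measured,
                                                 straight_tube):
    _, _, _, cl_sac, _ = sac_vessel_measured
    _, _, truth = straight_tube
    # compare against the analytic parent axis (y = z = 0)
    dev = np.linalg.norm(cl_sac.points[:, 1:], axis=1)
    assert dev.max() < 0.2  # 10% of the parent radius
    inflation = (cl_sac.radius.max() - 2.0) / 2.0
    assert inflation < 0.10


# ----------------------------------------------------------------------
# neck detection
# ----------------------------------------------------------------------
def test_plain_tube_has_no_neck(straight_tube):
    _, mesh, truth = straight_tube
    cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
    assert detect_neck(mesh, cl) is None


def test_neck_contour_matches_ground_truth(sac_vessel_measured):
    spec, mesh, truth, cl, neck = sac_vessel_measured
    assert neck is not None
    d, _ = cKDTree(truth.neck_contour).query(neck.points)
    assert d.mean() < spec.mesh_edge_target
    # plane normal close to the true sac axis
    assert abs(neck.plane_normal @ truth.neck_normal) > 0.98


def test_hemisphere_neck_diameter(hemisphere_vessel):
    spec, mesh, truth = hemisphere_vessel
    cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
    neck = detect_neck(mesh, cl)
    assert neck is not None
    N = neck.equivalent_diameter()
    assert N == pytest.approx(2 * spec.neck_radius,
                              abs=2 * spec.mesh_edge_target)


# ----------------------------------------------------------------------
# morphometry
# ----------------------------------------------------------------------
def test_measured_dhn_match_generator_ground_truth(sac_vessel_measured):
    spec, mesh, truth, cl, neck = sac_vessel_measured
    morph = compute_morphometry(mesh, neck)
    tol = 2 * spec.mesh_edge_target
    assert morph.D == pytest.approx(truth.D, abs=tol)
    assert morph.H == pytest.approx(truth.H, abs=tol)
    assert morph.N == pytest.approx(truth.N, abs=tol)


def test_hemisphere_morphometry_ratios(hemisphere_vessel):
    spec, mesh, truth = hemisphere_vessel
    cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
    morph = compute_morphometry(mesh, detect_neck(mesh, cl))
    # analytic hemisphere: H/N = 0.5, D/H = 2, D/N = 1
    assert morph.H_over_N == pytest.approx(0.5, abs=0.12)
    assert morph.D_over_H == pytest.approx(2.0, abs=0.4)
    assert morph.D_over_N == pytest.approx(1.0, abs=0.12)


def test_morphometry_requires_a_neck(straight_tube):
    _, mesh, _ = straight_tube
    with pytest.raises(NeckAbsentError):
        compute_morphometry(mesh, None)


def test_morphometry_is_rigid_invariant(sac_vessel_measured):
    spec, mesh, truth, cl, neck = sac_vessel_measured
    morph = compute_morphometry(mesh, neck)

    angle = 0.6
    rot = np.eye(4)
    rot[:3, :3] = np.array([
        [np.cos(angle), 0, np.sin(angle)],
        [0, 1, 0],
        [-np.sin(angle), 0, np.cos(angle)],
    ])
    rot[:3, 3] = [3.0, -7.0, 11.0]
    moved = mesh.transformed(rot)
    cl2 = extract_centerline(
        moved,
        rot[:3, :3] @ truth.inlet_center + rot[:3, 3],
        rot[:3, :3] @ truth.outlet_center + rot[:3, 3],
    )
    neck2 = detect_neck(moved, cl2)
    morph2 = compute_morphometry(moved, neck2)
    # detection re-runs from scratch; the measured values must agree to
    # well below the mesh scale, and identically-measured ratios to ~1e-6
    # would require identical contours, so compare at measurement precision
    assert morph2.D == pytest.approx(morph.D, abs=0.05)
    assert morph2.H == pytest.approx(morph.H, abs=0.1)
    assert morph2.N == pytest.approx(morph.N, abs=0.1)


def test_measurement_error_halves_with_mesh_refinement():
    # convergence to the closed-form sphere/cylinder truth is tested on the
    # unfilleted geometry: the junction fillet is a fixed modeled feature
    # whose (small) bias does not vanish with mesh size
    errs = []
    for edge in (0.5, 0.25):
        spec = SyntheticVesselSpec(parent_radius=2.0, sac_radius=3.0,
                                   neck_radius=1.5, mesh_edge_target=edge,
                                   seed=7, fillet_fraction=0.0)
        mesh, truth = generate_vessel(spec)
        cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
        morph = compute_morphometry(mesh, detect_neck(mesh, cl))
        errs.append(abs(morph.D - truth.D) + abs(morph.H - truth.H)
                    + abs(morph.N - truth.N))
    assert errs[1] <= 0.5 * errs[0]


# ----------------------------------------------------------------------
# ratio record
# ----------------------------------------------------------------------
def test_ratio_record_identity_case():
    m = AneurysmMorphometry.from_dimensions(5.0, 5.0, 5.0)
    assert m.rounded()["H_over_N"] == 1.0
    assert m.rounded()["D_over_H"] == 1.0
    assert m.rounded()["D_over_N"] == 1.0


def test_inconsistent_stored_ratio_is_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        AneurysmMorphometry(D=7.2, H=10.1, N=5.7, H_over_N=1.9,
                            D_over_H=0.71, D_over_N=1.26)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(D=st.floats(1.0, 20.0), H=st.floats(1.0, 20.0), N=st.floats(1.0, 20.0))
def test_ratios_always_consistent_with_dimensions(D, H, N):
    m = AneurysmMorphometry.from_dimensions(D, H, N)
    assert m.H_over_N * N == pytest.approx(H, rel=1e-9)
    assert m.D_over_H * H == pytest.approx(D, rel=1e-9)
    assert m.D_over_N * N == pytest.approx(D, rel=1e-9)
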