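"""Synthetic vessel generator: watertightness, ground truth, determinism;
constructed flow fields: divergence-freeness and stored ground truth."""

import dataclasses

import numpy as np
import pytest

from aneuflow.synthetic import (ConstructedFieldSpec, GeometryError,
                                SyntheticVesselSpec,
                                generate_constructed_field, generate_vessel)


@pytest.mark.parametrize("spec", [
    SyntheticVesselSpec(seed=0),
    SyntheticVesselSpec(centerline_curvature=0.05, seed=3),
    SyntheticVesselSpec(sac_radius=0.0, neck_radius=0.0, seed=2),
    SyntheticVesselSpec(sac_radius=2.5, neck_radius=1.0,
                        mesh_edge_target=0.4, seed=11),
], ids=["straight-sac", "curved-sac", "plain-tube", "narrow-neck"])
def test_generated_meshes_are_watertight_and_oriented(spec):
    mesh, truth = generate_vessel(spec)
    mesh.validate()          # edge-incidence = 2 everywhere, winding coherent
    assert mesh.volume() > 0


def test_same_seed_gives_byte_identical_vertices(sac_vessel):
    spec, mesh, _ = sac_vessel
    mesh2, _ = generate_vessel(spec)
    assert np.array_equal(mesh.vertices, mesh2.vertices)
    assert np.array_equal(mesh.faces, mesh2.faces)


def test_different_seed_jitters_vertices(sac_vessel):
    spec, mesh, _ = sac_vessel
    mesh2, truth2 = generate_vessel(dataclasses.replace(spec, seed=8))
    assert not np.array_equal(mesh.vertices, mesh2.vertices)
    assert truth2.D == pytest.approx(2 * spec.sac_radius)  # truth unchanged


def test_plain_tube_has_no_sac_ground_truth():
    spec = SyntheticVesselSpec(sac_radius=0.0, neck_radius=0.0, seed=5)
    mesh, truth = generate_vessel(spec)
    assert not truth.has_sac
    assert truth.D is None and truth.H is None and truth.N is None
    assert truth.sac_face_mask is None


def test_hemisphere_ground_truth_matches_closed_form(hemisphere_vessel):
    spec, _, truth = hemisphere_vessel
    r = spec.sac_radius
    assert truth.H == pytest.approx(r, abs=1e-12)
    assert truth.D == pytest.approx(2 * r, abs=1e-12)
    assert truth.N == pytest.approx(2 * r, abs=1e-12)


def test_sac_reaching_lumen_axis_is_rejected():
    spec = SyntheticVesselSpec(parent_radius=2.0, sac_radius=2.0,
                               neck_radius=2.0, mesh_edge_target=0.3)
    with pytest.raises(GeometryError, match="self-intersection"):
        generate_vessel(spec)


def test_detached_sac_is_rejected():
    spec = SyntheticVesselSpec(sac_radius=3.0, neck_radius=1.0,
                               sac_height_offset=1.0)
    with pytest.raises(GeometryError, match="detached"):
        generate_vessel(spec)


def test_invalid_edge_target_rejected():
    with pytest.raises(GeometryError):
        SyntheticVesselSpec(mesh_edge_target=2.5).validate()


# ----------------------------------------------------------------------
# constructed fields
# ----------------------------------------------------------------------
def test_constructed_field_conserves_mass_over_any_subbox():
    """Net flux through a control box inside the field vanishes."""
    cf = generate_constructed_field(
        ConstructedFieldSpec(n_vortices_per_step=(2,), jet_width_fraction=0.4,
                             grid_resolution=60)
    )
    f = cf.field
    lo, hi = np.array([1.0, 1.0, 0.4]), np.array([9.0, 9.0, 1.6])
    n_s = 60
    net = 0.0
    gross = 0.0
    for ax in range(3):
        for side, sign in ((lo, -1.0), (hi, 1.0)):
            axes = [a for a in range(3) if a != ax]
            g0 = np.linspace(lo[axes[0]], hi[axes[0]], n_s)
            g1 = np.linspace(lo[axes[1]], hi[axes[1]], n_s)
            A, B = np.meshgrid(g0, g1, indexing="ij")
            pts = np.empty((n_s * n_s, 3))
            pts[:, ax] = side[ax]
            pts[:, axes[0]] = A.ravel()
            pts[:, axes[1]] = B.ravel()
            u = f.velocity_at(pts, 0, outside="zero")
            cell = (g0[1] - g0[0]) * (g1[1] - g1[0])
            contrib = sign * u[:, ax].sum() * cell
            net += contrib
            gross += np.abs(u[:, ax]).sum() * cell
    assert abs(net) < 0.01 * max(gross, 1e-12)


def test_constructed_field_records_ground_truth():
    spec = ConstructedFieldSpec(n_vortices_per_step=(1, 2, 2, 1),
                                jet_direction_changes=True,
                                jet_width_fraction=0.35, seed=4)
    cf = generate_constructed_field(spec)
    assert cf.truth["vortex_counts"] == [1, 2, 2, 1]
    assert cf.truth["jet_direction_changed"] is True
    assert cf.truth["jet_width_fraction"] == pytest.approx(0.35)
    assert cf.field.n_steps == 4
    assert np.all(np.diff(cf.field.times) > 0)


def test_grid_too_coarse_for_vortex_count_is_rejected():
    with pytest.raises(ValueError, match="too coarse"):
        ConstructedFieldSpec(n_vortices_per_step=(4,),
                             grid_resolution=16).validate()


def test_jet_width_fraction_bounds():
    with pytest.raises(ValueError):
        ConstructedFieldSpec(jet_width_fraction=0.0).validate()
    with pytest.raises(ValueError):
        ConstructedFieldSpec(jet_width_fraction=1.2).validate()
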