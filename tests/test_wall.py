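"""Wall shear stress, WSS gradient, and section statistics."""

import dataclasses

import numpy as np
import pytest

from aneuflow.fields import FlowField, TetInterpolator
from aneuflow.solver.flow import FluidProperties, section_flux
from aneuflow.solver.volume import WALL, structured_tube_mesh
from aneuflow.wall import (SectionError, SectionStats, WallField,
                           compare_states, compute_wss, compute_wssg,
                           section_stats)


@pytest.fixture(scope="module")
def poiseuille_wall(poiseuille_runs):
    runs, fluid, bc = poiseuille_runs
    vm, field = runs["fine"]
    wall = compute_wss(field, vm, fluid, 0)
    return vm, field, fluid, wall


def _interior(wall):
    return (wall.centers[:, 0] > 1.5) & (wall.centers[:, 0] < 6.5)


# ----------------------------------------------------------------------
# WSS
# ----------------------------------------------------------------------
def test_poiseuille_wss_matches_closed_form(poiseuille_wall):
    vm, field, fluid, wall = poiseuille_wall
    Q, A = section_flux(vm, field.velocities[0], np.array([4.0, 0, 0]),
                        np.array([1.0, 0, 0]), return_area=True)
    R_eff = np.sqrt(A / np.pi)
    wss_theory = (4 * fluid.dynamic_viscosity * (Q * 1e-9)
                  / (np.pi * (R_eff * 1e-3) ** 3))
    m = _interior(wall)
    assert wall.wss_mag[m].mean() == pytest.approx(wss_theory, rel=0.05)
    # uniform around the tube
    assert wall.wss_mag[m].std() / wall.wss_mag[m].mean() < 0.05


def test_zero_flow_gives_zero_wss(poiseuille_wall):
    vm, field, fluid, _ = poiseuille_wall
    still = FlowField(vm.nodes, vm.tets,
                      np.zeros_like(field.velocities),
                      np.zeros_like(field.pressures), field.times, 0)
    wall0 = compute_wss(still, vm, fluid, 0)
    assert np.abs(wall0.wss_mag).max() < 1e-12


def test_wss_is_linear_in_viscosity(poiseuille_wall):
    vm, field, fluid, wall = poiseuille_wall
    doubled = dataclasses.replace(
        fluid, dynamic_viscosity=2 * fluid.dynamic_viscosity)
    wall2 = compute_wss(field, vm, doubled, 0)
    assert np.allclose(wall2.wss_mag, 2 * wall.wss_mag, rtol=1e-12)


def test_step_out_of_range_rejected(poiseuille_wall):
    vm, field, fluid, _ = poiseuille_wall
    with pytest.raises(IndexError):
        compute_wss(field, vm, fluid, field.n_steps)


# ----------------------------------------------------------------------
# WSSG
# ----------------------------------------------------------------------
def test_uniform_wall_field_has_zero_wssg(poiseuille_wall):
    vm, _, _, wall = poiseuille_wall
    uni = WallField(wall.facet_tris, wall.centers, wall.normals, wall.areas,
                    wall.wss_vec, np.ones_like(wall.wss_mag), wall.pressure, 0)
    uni = compute_wssg(uni, vm)
    assert uni.wssg.max() <= 1e-9


def test_linear_axial_ramp_recovered(poiseuille_wall):
    vm, _, _, wall = poiseuille_wall
    g = 2.0  # Pa/mm
    vert = g * vm.nodes[:, 0]
    ramp = compute_wssg(
        WallField(wall.facet_tris, wall.centers, wall.normals, wall.areas,
                  wall.wss_vec, wall.wss_mag, wall.pressure, 0),
        vm, vertex_values=vert)
    m = _interior(ramp)
    assert np.abs(ramp.wssg[m] - g).max() < 0.05 * g


def test_wssg_invariant_under_rigid_rotation(poiseuille_wall):
    vm, _, _, wall = poiseuille_wall
    vert = 1.5 * vm.nodes[:, 0] - 0.5 * vm.nodes[:, 2]
    base = compute_wssg(
        WallField(wall.facet_tris, wall.centers, wall.normals, wall.areas,
                  wall.wss_vec, wall.wss_mag, wall.pressure, 0),
        vm, vertex_values=vert)
    a = 0.9
    R = np.array([[np.cos(a), -np.sin(a), 0],
                  [np.sin(a), np.cos(a), 0],
                  [0, 0, 1]])
    vm_rot = dataclasses.replace(vm, nodes=vm.nodes @ R.T)
    wall_rot = WallField(wall.facet_tris, wall.centers @ R.T,
                         wall.normals @ R.T, wall.areas, wall.wss_vec @ R.T,
                         wall.wss_mag, wall.pressure, 0)
    rot = compute_wssg(wall_rot, vm_rot, vertex_values=vert)
    assert np.allclose(rot.wssg, base.wssg, atol=1e-10)


# ----------------------------------------------------------------------
# section statistics
# ----------------------------------------------------------------------
def test_uniform_field_stats_have_zero_sd(poiseuille_wall):
    vm, field, fluid, wall = poiseuille_wall
    uni_wall = WallField(wall.facet_tris, wall.centers, wall.normals,
                         wall.areas, wall.wss_vec,
                         np.full_like(wall.wss_mag, 3.3),
                         np.full_like(wall.pressure, 7.0), 0)
    uni_field = FlowField(vm.nodes, vm.tets,
                          np.full_like(field.velocities, 2.0),
                          field.pressures, field.times, 0)
    for n_points in (4, 8):
        s = section_stats(uni_field, uni_wall, vm, np.array([4.0, 0, 0]),
                          np.array([1.0, 0, 0]), "mid", n_points=n_points)
        assert s.wss_mean == pytest.approx(3.3)
        assert s.wss_sd == 0.0
        assert s.pressure_mean == pytest.approx(7.0)
        assert s.velocity_mean == pytest.approx(np.sqrt(12.0), rel=1e-9)
        assert s.velocity_sd == pytest.approx(0.0, abs=1e-9)


def test_poiseuille_section_four_points(poiseuille_wall):
    vm, field, fluid, wall = poiseuille_wall
    Q, A = section_flux(vm, field.velocities[0], np.array([4.0, 0, 0]),
                        np.array([1.0, 0, 0]), return_area=True)
    wss_theory = (4 * fluid.dynamic_viscosity * (Q * 1e-9)
                  / (np.pi * (np.sqrt(A / np.pi) * 1e-3) ** 3))
    s = section_stats(field, wall, vm, np.array([4.0, 0, 0]),
                      np.array([1.0, 0, 0]), "mid", n_points=4)
    assert s.n_points == 4
    assert s.wss_mean == pytest.approx(wss_theory, rel=0.06)
    # rotational symmetry: tiny spread regardless of angular start
    assert s.wss_sd < 0.05 * s.wss_mean


def test_four_point_arithmetic_sample_sd():
    # the 1,2,3,4 Pa example: mean 2.5, sample SD ~1.29
    from aneuflow.wall import _sample_sd
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    assert vals.mean() == pytest.approx(2.5)
    assert _sample_sd(vals) == pytest.approx(1.29, abs=0.01)


def test_plane_missing_the_lumen_raises(poiseuille_wall):
    vm, field, fluid, wall = poiseuille_wall
    with pytest.raises(SectionError):
        section_stats(field, wall, vm, np.array([40.0, 0, 0]),
                      np.array([1.0, 0, 0]), "off-domain")


# ----------------------------------------------------------------------
# state comparison
# ----------------------------------------------------------------------
def _stats(label, wss, vel):
    return SectionStats(label=label, n_points=4, wss_mean=wss, wss_sd=0.1,
                        pressure_mean=100.0, pressure_sd=1.0,
                        velocity_mean=vel, velocity_sd=1.0)


def test_identical_states_give_unit_ratios():
    a = {"dome": _stats("dome", 2.0, 100.0),
         "neck": _stats("neck", 2.0, 100.0)}
    p = {"formation_site": _stats("formation_site", 3.0, 200.0),
         "adjacent": _stats("adjacent", 3.0, 200.0)}
    rep = compare_states(a, p)
    assert rep["ratios"]["dome_over_neck_wss"] == pytest.approx(1.0)
    assert rep["ratios"]["site_over_adjacent_wss"] == pytest.approx(1.0)


def test_empty_stats_rejected():
    with pytest.raises(ValueError):
        compare_states({}, {"adjacent": _stats("adjacent", 1.0, 1.0)})
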