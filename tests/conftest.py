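"""Shared fixtures: synthetic geometries and (expensive) solver runs.

Solver fixtures are session-scoped so the Poiseuille, pulsatile and
retrospective runs are computed once and shared between the unit tests and
the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from aneuflow.morphometry import detect_neck, extract_centerline
from aneuflow.solver.flow import (FlowBoundaryConditions, FluidProperties,
                                  SolverConfig, solve_flow, solve_steady)
from aneuflow.solver.volume import structured_tube_mesh
from aneuflow.synthetic import SyntheticVesselSpec, generate_vessel

RE100_PEAK_CMS = 2 * 100 * 0.35 / (1.060 * 0.2) / 10  # cm/s, Re=100 in R=1mm


@pytest.fixture(scope="session")
def straight_tube():
    spec = SyntheticVesselSpec(parent_radius=2.0, parent_length=30.0,
                               sac_radius=0.0, neck_radius=0.0,
                               mesh_edge_target=0.35, seed=2)
    mesh, truth = generate_vessel(spec)
    return spec, mesh, truth


@pytest.fixture(scope="session")
def sac_vessel():
    spec = SyntheticVesselSpec(parent_radius=2.0, sac_radius=3.0,
                               neck_radius=1.5, mesh_edge_target=0.35,
                               seed=7)
    mesh, truth = generate_vessel(spec)
    return spec, mesh, truth


@pytest.fixture(scope="session")
def sac_vessel_measured(sac_vessel):
    spec, mesh, truth = sac_vessel
    cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
    neck = detect_neck(mesh, cl)
    return spec, mesh, truth, cl, neck


@pytest.fixture(scope="session")
def hemisphere_vessel():
    spec = SyntheticVesselSpec(parent_radius=2.0, sac_radius=1.5,
                               neck_radius=1.5, mesh_edge_target=0.3, seed=1)
    mesh, truth = generate_vessel(spec)
    return spec, mesh, truth


def _poiseuille_bc():
    # steady flow at Re = 100 in a radius-1 mm tube: peak speed 2x mean
    u_mean = 100 * 3.5e-3 / (1060 * 0.002)  # m/s
    peak_cms = 2 * u_mean * 100
    return FlowBoundaryConditions(systolic_speed=peak_cms,
                                  diastolic_speed=peak_cms, heart_rate=60)


@pytest.fixture(scope="session")
def poiseuille_runs():
    """Steady Re=100 cylinder runs at two resolutions (coarse, fine)."""
    fluid = FluidProperties()
    bc = _poiseuille_bc()
    out = {}
    for label, n_radial in (("coarse", 4), ("fine", 6)):
        vm = structured_tube_mesh(1.0, 8.0, n_radial=n_radial)
        cfg = SolverConfig(target_cell_size=vm.pitch)
        field = solve_steady(vm, fluid, bc, cfg)
        out[label] = (vm, field)
    return out, fluid, bc


@pytest.fixture(scope="session")
def pulsatile_run():
    """Low-Womersley pulsatile tube run, 100 steps/cycle, 2 cycles."""
    fluid = FluidProperties()
    bc = FlowBoundaryConditions(systolic_speed=30.0, diastolic_speed=10.0,
                                heart_rate=79)
    vm = structured_tube_mesh(0.5, 3.0, n_radial=4)
    cfg = SolverConfig(steps_per_cycle=100, n_cycles=2,
                       target_cell_size=vm.pitch)
    field = solve_flow(vm, fluid, bc, cfg)
    return vm, field, fluid, bc, cfg


RETRO_CFG = {
    "vessel": {"mesh_edge_target": 0.4},
    "solver": {"steps_per_cycle": 50, "n_cycles": 2,
               "target_cell_size": 0.55},
}


@pytest.fixture(scope="session")
def retrospective_report():
    from aneuflow.pipeline import run_retrospective

    return run_retrospective(RETRO_CFG)
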