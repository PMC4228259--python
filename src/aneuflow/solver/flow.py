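"""Unsteady incompressible Newtonian flow in the meshed lumen.

Semi-implicit monolithic stepping on MINI-stabilized P1/P1 tetrahedra:
velocity and pressure are solved together each step from

    (rho M/dt + mu K) u^{n+1} + C p^{n+1} = rho M/dt u_a
    D u^{n+1} + S p^{n+1} = 0

where u_a is the explicitly advected (CFL-sub-cycled, streamline-stabilized)
velocity, C/D the first-derivative operators, and S the pressure
stabilization obtained by exact static condensation of the MINI bubble —
no tunable constant.  The system matrix is constant in time and factorized
once per run, so a cardiac cycle of 100 steps costs 100 triangular solves.
There is no projection splitting error and mass is conserved to the
stabilized weak tolerance at every step.

Boundary conditions: no-slip walls, Doppler-derived pulsatile inlet velocity
(raised-cosine waveform between the printed diastolic and systolic speeds at
the given heart rate), zero-gauge-pressure outlet.  One cardiac cycle is
resolved with ``steps_per_cycle`` time steps (default 100) and readouts are
taken at peak systole; two cycles are run by default and the first discarded
to wash out the initial transient.  Doppler speeds are supplied in cm/s;
stored fields are mm/s and Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..fields import FlowField
from . import fem
from .volume import VolumeMesh

MM = 1e-3  # mm -> m


class ConvergenceError(RuntimeError):
    pass


class CFLError(ValueError):
    def __init__(self, msg: str, suggested_dt: float):
        super().__init__(msg)
        self.suggested_dt = suggested_dt


@dataclass(frozen=True)
class FluidProperties:
    """Blood as an incompressible Newtonian fluid (community constants)."""

    density: float = 1060.0            # kg/m^3
    dynamic_viscosity: float = 3.5e-3  # Pa s

    def validate(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class FlowBoundaryConditions:
    """Doppler-style inlet + gauge-pressure outlet.

    Speeds are in cm/s as printed by ultrasound reports; heart rate in bpm.
    """

    systolic_speed: float              # cm/s
    diastolic_speed: float             # cm/s
    heart_rate: float                  # bpm
    inlet_profile: str = "parabolic"   # or "flat"
    outlet_pressure: float = 0.0       # Pa (gauge)

    def validate(self) -> None:
        if not self.systolic_speed >= self.diastolic_speed > 0:
            raise ValueError("need systolic_speed >= diastolic_speed > 0")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.inlet_profile not in ("parabolic", "flat"):
            raise ValueError("inlet_profile must be 'parabolic' or 'flat'")

    @property
    def period(self) -> float:
        """Cardiac period in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class SolverConfig:
    steps_per_cycle: int = 100
    n_cycles: int = 2
    target_cell_size: float = 0.4      # mm
    convergence_tol: float = 2e-5
    seed: int = 0
    max_advection_subcycles: int = 400

    def validate(self) -> None:
        if self.steps_per_cycle < 1:
            raise ValueError("steps_per_cycle must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


def synthesize_waveform(bc: FlowBoundaryConditions, config: SolverConfig):
    """Inlet speed per step over one cycle: (times s, speeds mm/s).

    Raised cosine from diastole at t=0 to systole at t=T/2 and back; max is
    exactly the systolic speed, min the diastolic speed.
    """
    bc.validate()
    config.validate()
    T = bc.period
    k = np.arange(config.steps_per_cycle)
    t = k * T / config.steps_per_cycle
    sys_mm = 10.0 * bc.systolic_speed
    dia_mm = 10.0 * bc.diastolic_speed
    speeds = dia_mm + (sys_mm - dia_mm) * 0.5 * (
        1.0 - np.cos(2 * np.pi * k / config.steps_per_cycle)
    )
    return t, speeds


def _with_dirichlet_rows(A: sp.spmatrix, rows: np.ndarray) -> sp.csr_matrix:
    """Replace the given rows of A by identity rows (sparse, vectorized)."""
    n = A.shape[0]
    keep = np.ones(n)
    keep[rows] = 0.0
    ident = np.zeros(n)
    ident[rows] = 1.0
    return (sp.diags(keep) @ A.tocsr() + sp.diags(ident)).tocsr()


def _zero_dirichlet_rows(A: sp.spmatrix, rows: np.ndarray) -> sp.csr_matrix:
    n = A.shape[0]
    keep = np.ones(n)
    keep[rows] = 0.0
    return (sp.diags(keep) @ A.tocsr()).tocsr()


def _inlet_velocity(vmesh: VolumeMesh, bc: FlowBoundaryConditions,
                    speed_mms: float) -> np.ndarray:
    """Nodal inlet velocity (m/s) for the given peak speed in mm/s."""
    nodes = vmesh.inlet_nodes()
    c, n = vmesh.inlet_center, vmesh.inlet_normal
    direction = -n  # into the domain
    rel = vmesh.nodes[nodes] - c
    r = np.linalg.norm(rel - np.outer(rel @ n, n), axis=1)
    R = vmesh.inlet_radius
    if bc.inlet_profile == "parabolic":
        shape = np.clip(1.0 - (r / R) ** 2, 0.0, None)
    else:
        shape = np.ones_like(r)
    u = np.zeros((len(nodes), 3))
    u[:] = direction
    u *= (speed_mms * MM * shape)[:, None]
    return u


def mini_stabilization(ops: fem.P1Operators, mu: float) -> sp.csr_matrix:
    """Pressure stabilization from exact MINI-bubble static condensation.

    For the cubic bubble b = 256 l0 l1 l2 l3 the viscous bubble block is
    diagonal per element and decoupled from the P1 velocities, so it
    condenses exactly into S = sum_T tau_T (grad q, grad p)_T with
    tau_T = (int_T b)^2 / (mu int_T |grad b|^2) / V_T
          = V_T * (15120 / 840^2) / (mu sum_i |g_i|^2) / V_T.
    """
    g2 = np.einsum("mcd,mcd->m", ops.grads, ops.grads)
    tau = (15120.0 / 840.0**2) / (mu * g2)  # per-element weight (times V)
    tets = ops.tets
    n = ops.n_nodes
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    kv = np.einsum("mid,mjd,m->mij", ops.grads, ops.grads,
                   tau * ops.volumes)
    return sp.coo_matrix((kv.ravel(), (rows, cols)), shape=(n, n)).tocsr()


class MonolithicSolver:
    """Constant-matrix semi-implicit Navier-Stokes stepper on one mesh."""

    def __init__(self, vmesh: VolumeMesh, fluid: FluidProperties,
                 bc: FlowBoundaryConditions, config: SolverConfig,
                 dt: float):
        fluid.validate()
        bc.validate()
        config.validate()
        self.vmesh = vmesh
        self.fluid = fluid
        self.bc = bc
        self.config = config
        self.dt = dt
        self.ops = fem.assemble(vmesh.nodes * MM, vmesh.tets)
        ops = self.ops
        n = ops.n_nodes
        self.n = n

        self.wall = vmesh.wall_nodes()
        self.inlet = vmesh.inlet_nodes()
        self.outlet = vmesh.outlet_nodes()
        # rim nodes sit on both cap and wall circle; the parabolic profile
        # vanishes there so inlet Dirichlet and no-slip agree
        self.dir_nodes = np.unique(np.concatenate([self.wall, self.inlet]))

        rho, mu = fluid.density, fluid.dynamic_viscosity
        S = mini_stabilization(ops, mu)
        A_uu = sp.diags(rho * ops.M_lumped / dt) + mu * ops.K
        zero = sp.csr_matrix((n, n))
        blocks = []
        for d in range(3):
            row = [zero] * 4
            row[d] = _with_dirichlet_rows(A_uu, self.dir_nodes)
            row[3] = _zero_dirichlet_rows(ops.C[d], self.dir_nodes)
            blocks.append(row)
        blocks.append([
            _zero_dirichlet_rows(ops.C[0], self.outlet),
            _zero_dirichlet_rows(ops.C[1], self.outlet),
            _zero_dirichlet_rows(ops.C[2], self.outlet),
            _with_dirichlet_rows(S, self.outlet),
        ])
        self.A_lu = spla.splu(sp.bmat(blocks, format="csc"))

        p = vmesh.nodes[vmesh.tets] * MM
        e = np.linalg.norm(
            p[:, [0, 0, 0, 1, 1, 2]] - p[:, [1, 2, 3, 2, 3, 3]], axis=2
        )
        self.h_cell = e.min(axis=1)

    def advect(self, u: np.ndarray) -> np.ndarray:
        """Explicit sub-cycled advection of u over one time step (m/s)."""
        ops = self.ops
        dt = self.dt
        u_cell = np.linalg.norm(u[ops.tets].mean(axis=1), axis=1)
        if float(u_cell.max()) > 0:
            dt_cfl = 0.3 * float(np.min(self.h_cell / (u_cell + 1e-12)))
            m = max(1, int(np.ceil(dt / dt_cfl)))
        else:
            m = 1
        if m > self.config.max_advection_subcycles:
            raise CFLError(
                f"advection needs {m} subcycles per step; reduce the time "
                "step",
                suggested_dt=dt_cfl * self.config.max_advection_subcycles,
            )
        ua = u.copy()
        for _ in range(m):
            ua = ua - (dt / m) * ops.advection(ua, self.h_cell)
            ua[self.wall] = 0.0
        return ua

    def step(self, u: np.ndarray, inlet_speed_mms: float,
             advect: bool = True):
        """Advance one time step; returns (u m/s, p Pa)."""
        ops = self.ops
        rho = self.fluid.density
        ua = self.advect(u) if advect else u
        uin = _inlet_velocity(self.vmesh, self.bc, inlet_speed_mms)
        rhs = np.zeros(4 * self.n)
        for d in range(3):
            rhs[d * self.n: (d + 1) * self.n] = (
                rho * ops.M_lumped / self.dt * ua[:, d]
            )
            rhs[d * self.n + self.dir_nodes] = 0.0
            rhs[d * self.n + self.inlet] = uin[:, d]
        rhs[3 * self.n + self.outlet] = self.bc.outlet_pressure
        sol = self.A_lu.solve(rhs)
        u_new = sol[: 3 * self.n].reshape(3, self.n).T.copy()
        p_new = sol[3 * self.n:].copy()
        return u_new, p_new


def solve_flow(vmesh: VolumeMesh, fluid: FluidProperties,
               bc: FlowBoundaryConditions, config: SolverConfig) -> FlowField:
    """Pulsatile flow over ``n_cycles`` cardiac cycles; final cycle stored.

    Returns a :class:`FlowField` (velocities mm/s, pressures Pa) sampled at
    every step of the last cycle, with ``peak_systole_index`` at the inlet
    waveform argmax.
    """
    times, speeds = synthesize_waveform(bc, config)
    dt = bc.period / config.steps_per_cycle
    solver = MonolithicSolver(vmesh, fluid, bc, config, dt)
    n = solver.n
    u = np.zeros((n, 3))

    S = config.steps_per_cycle
    stored_u = np.zeros((S, n, 3))
    stored_p = np.zeros((S, n))
    for cycle in range(config.n_cycles):
        for k in range(S):
            u, p = solver.step(u, speeds[k])
            if cycle == config.n_cycles - 1:
                stored_u[k] = u
                stored_p[k] = p
    return FlowField(
        nodes=vmesh.nodes,
        tets=vmesh.tets,
        velocities=stored_u / MM,  # m/s -> mm/s
        pressures=stored_p,
        times=times + (config.n_cycles - 1) * bc.period,
        peak_systole_index=int(np.argmax(speeds)),
    )


def solve_steady(vmesh: VolumeMesh, fluid: FluidProperties,
                 bc: FlowBoundaryConditions, config: SolverConfig,
                 max_steps: int = 1500) -> FlowField:
    """March to steady state at the systolic inlet speed.

    The monolithic step has no splitting error, so the converged state is
    the steady stabilized Navier-Stokes solution regardless of dt.  Stops
    when the relative velocity change per step drops below
    ``config.convergence_tol``.
    """
    speed = 10.0 * bc.systolic_speed  # mm/s
    dt = 2.0 * (vmesh.pitch * MM) / max(speed * MM, 1e-12)
    solver = MonolithicSolver(vmesh, fluid, bc, config, dt)
    u = np.zeros((solver.n, 3))
    p = np.zeros(solver.n)
    num = den = None
    for _ in range(max_steps):
        u_new, p = solver.step(u, speed)
        num = float(np.abs(u_new - u).max())
        den = max(float(np.abs(u_new).max()), 1e-30)
        u = u_new
        if num / den < config.convergence_tol:
            break
    else:
        raise ConvergenceError(
            f"steady state not reached in {max_steps} steps "
            f"(residual {num / den:.2e})"
        )
    return FlowField(
        nodes=vmesh.nodes, tets=vmesh.tets,
        velocities=(u / MM)[None, :, :], pressures=p[None, :],
        times=np.array([0.0]), peak_systole_index=0,
    )


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def section_flux(vmesh: VolumeMesh, u_mms: np.ndarray, origin: np.ndarray,
                 normal: np.ndarray, return_area: bool = False):
    """Volumetric flux (mm^3/s) of nodal velocity through a cross-section.

    Exact for the P1 field: each cut tet contributes its intersection
    polygon's area times the interpolated velocity at the polygon centroid.
    With ``return_area`` also returns the cross-section area (mm^2).
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = (vmesh.nodes - origin) @ normal
    # nudge exactly-on-plane nodes so every element is cleanly cut
    scale = max(float(np.abs(d).max()), 1.0)
    d = np.where(np.abs(d) < 1e-9 * scale, 1e-9 * scale, d)
    dt = d[vmesh.tets]
    cut = (dt.min(axis=1) < 0) & (dt.max(axis=1) > 0)
    flux = 0.0
    area_total = 0.0
    for tet, dv in zip(vmesh.tets[cut], dt[cut]):
        pts = []
        vals = []
        for a in range(4):
            for b in range(a + 1, 4):
                if (dv[a] > 0) != (dv[b] > 0):
                    t = dv[a] / (dv[a] - dv[b])
                    pts.append(
                        vmesh.nodes[tet[a]]
                        + t * (vmesh.nodes[tet[b]] - vmesh.nodes[tet[a]])
                    )
                    vals.append(
                        u_mms[tet[a]] + t * (u_mms[tet[b]] - u_mms[tet[a]])
                    )
        if len(pts) < 3:
            continue
        pts = np.asarray(pts)
        vals = np.asarray(vals)
        c = pts.mean(axis=0)
        ref = pts[0] - c
        ref -= normal * (ref @ normal)
        ref /= max(np.linalg.norm(ref), 1e-30)
        ref2 = np.cross(normal, ref)
        ang = np.arctan2((pts - c) @ ref2, (pts - c) @ ref)
        order = np.argsort(ang)
        pts, vals = pts[order], vals[order]
        for i in range(1, len(pts) - 1):
            area_vec = 0.5 * np.cross(pts[i] - pts[0], pts[i + 1] - pts[0])
            area = np.linalg.norm(area_vec)
            u_c = (vals[0] + vals[i] + vals[i + 1]) / 3.0
            flux += float(u_c @ normal) * area
            area_total += area
    if return_area:
        return flux, area_total
    return flux
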