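"""End-to-end retrospective study: aneurysm state, repair, pre-aneurysm state.

Given a synthetic vessel specification and Doppler boundary conditions, the
pipeline measures morphometry, virtually removes the sac, simulates pulsatile
flow in both the aneurysm and the repaired ("pre-aneurysm") lumen, extracts
wall metrics at peak systole, classifies the intra-saccular flow pattern, and
tabulates the comparison between the two states — the computational analogue
of studying a patient's hemodynamics before and after aneurysm formation.

Every stage failure aborts with the stage name; reports embed the config
hash and seed so identical configs reproduce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import config as cfgmod
from .morphometry import (compute_morphometry, detect_neck,
                          extract_centerline)
from .patterns import SacRegion, classify_pattern
from .repair import repair_vessel
from .solver.flow import section_flux, solve_flow
from .solver.volume import mesh_volume
from .synthetic import generate_vessel
from .wall import compare_states, compute_wss, compute_wssg, region_stats, \
    section_stats


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_retrospective(cfg: dict | None = None,
                      out_dir: str | Path | None = None) -> dict:
    """Run the full study; returns (and optionally writes) the report dict."""
    cfg = cfgmod.validate_config(cfg)
    t_start = time.time()
    report: dict = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": int(cfg["vessel"]["seed"]),
    }

    with _stage("synthesize_vessel"):
        spec = cfgmod.vessel_spec(cfg)
        mesh, truth = generate_vessel(spec)
        if not truth.has_sac:
            raise ValueError("the retrospective study needs an aneurysm sac")

    with _stage("morphometry"):
        cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
        neck = detect_neck(mesh, cl)
        if neck is None:
            raise ValueError("no aneurysm neck detected on the vessel")
        morph = compute_morphometry(mesh, neck)
        report["morphometry"] = {**morph.to_dict(), "rounded": morph.rounded()}

    with _stage("surface_repair"):
        repaired = repair_vessel(mesh, neck)
        report["repair"] = {
            "original_volume_mm3": mesh.volume(),
            "repaired_volume_mm3": repaired.volume(),
            "watertight": repaired.is_watertight(),
        }

    fluid = cfgmod.fluid_properties(cfg)
    bc = cfgmod.boundary_conditions(cfg)
    scfg = cfgmod.solver_config(cfg)
    caps = dict(inlet=(truth.inlet_center, truth.inlet_normal),
                outlet=(truth.outlet_center, truth.outlet_normal))

    with _stage("simulate_aneurysm_state"):
        vm_a = mesh_volume(mesh, scfg.target_cell_size, **caps)
        field_a = solve_flow(vm_a, fluid, bc, scfg)
        k_peak = field_a.peak_systole_index

    with _stage("simulate_preaneurysm_state"):
        vm_p = mesh_volume(repaired, scfg.target_cell_size, **caps)
        field_p = solve_flow(vm_p, fluid, bc, scfg)

    with _stage("wall_metrics"):
        wall_a = compute_wssg(compute_wss(field_a, vm_a, fluid, k_peak), vm_a)
        wall_p = compute_wssg(compute_wss(field_p, vm_p, fluid, k_peak), vm_p)

        n_hat = neck.plane_normal
        p0 = neck.plane_point
        flow_dir = truth.outlet_center - truth.inlet_center
        flow_dir -= n_hat * (flow_dir @ n_hat)
        flow_dir /= np.linalg.norm(flow_dir)
        H = morph.H
        height_a = (wall_a.centers - p0) @ n_hat
        sac_mask = height_a > 0.05 * H
        distal_mask = sac_mask & ((wall_a.centers - p0) @ flow_dir > 0)

        stats_a = {}
        for label, frac, mask in (
            ("neck", 0.15, sac_mask),
            ("body", 0.5, sac_mask),
            ("dome", 0.85, sac_mask),
        ):
            stats_a[label] = section_stats(
                field_a, wall_a, vm_a, p0 + frac * H * n_hat, n_hat, label,
                region_mask=mask,
            )
        stats_a["distal_neck"] = section_stats(
            field_a, wall_a, vm_a, p0 + 0.15 * H * n_hat, n_hat,
            "distal_neck", region_mask=distal_mask,
        )

        # pre-aneurysm: formation site = repaired patch footprint; adjacent =
        # a same-width ring of parent wall upstream of the site
        N_rad = morph.N / 2.0
        rel = wall_p.centers - p0
        ax = rel @ flow_dir
        lateral = rel - np.outer(ax, flow_dir)
        lat_n = lateral @ n_hat
        site_mask = (np.abs(ax) < N_rad) & (lat_n > -0.5 * N_rad)
        adj_mask = (ax > -4.0 * N_rad) & (ax < -2.0 * N_rad)
        stats_p = {
            "formation_site": region_stats(wall_p, site_mask, field_p,
                                           "formation_site"),
            "adjacent": region_stats(wall_p, adj_mask, field_p, "adjacent"),
        }
        comparison = compare_states(stats_a, stats_p)
        report["wall_metrics"] = comparison
        report["peak_systole_index"] = int(k_peak)
        report["peak_inlet_flux_mm3_s"] = float(section_flux(
            vm_a, field_a.velocities[k_peak],
            truth.inlet_center + 1.0 * (-truth.inlet_normal),
            -truth.inlet_normal,
        ))

    with _stage("flow_pattern"):
        trans = flow_dir
        region = SacRegion(
            neck_point=p0 + 0.02 * H * n_hat,
            neck_normal=n_hat,
            transverse_dir=trans,
            slice_normal=np.cross(n_hat, trans),
            height=H,
            half_width=0.75 * morph.D,
        )
        steps = list(range(0, field_a.n_steps,
                           max(1, field_a.n_steps // 20)))
        pattern = classify_pattern(field_a, region, steps=steps)
        report["flow_pattern"] = pattern.to_dict()

    report["runtime_s"] = round(time.time() - t_start, 1)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "mesh").mkdir(parents=True, exist_ok=True)
        (out / "report").mkdir(parents=True, exist_ok=True)
        mesh.save(out / "mesh" / "aneurysm.stl")
        repaired.save(out / "mesh" / "preaneurysm.stl")
        truth.save(out / "mesh" / "ground_truth.json")
        (out / "report" / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_jsonable)
        )
        if cfg["output"]["write_vtk"]:
            from .vtkio import write_tet_grid, write_tri_surface
            (out / "fields").mkdir(exist_ok=True)
            write_tet_grid(
                out / "fields" / "aneurysm_peak.vtk", vm_a.nodes, vm_a.tets,
                point_scalars={"Pressure": field_a.pressures[k_peak]},
                point_vectors={"Velocity": field_a.velocities[k_peak]},
            )
            write_tri_surface(
                out / "fields" / "aneurysm_wall.vtk", vm_a.nodes,
                wall_a.facet_tris,
                cell_scalars={"WSS": wall_a.wss_mag, "WSSG": wall_a.wssg,
                              "Pressure": wall_a.pressure},
            )
    return report


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
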