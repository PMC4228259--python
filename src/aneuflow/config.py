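"""Configuration schema for the retrospective pipeline.

YAML/dict configs are validated against an explicit schema: unknown keys are
rejected, missing keys take documented defaults, and all violations are
reported at once.  The default boundary conditions are the ruptured-case
carotid Doppler values (67.6/26.2 cm/s at 79 bpm).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .solver.flow import FlowBoundaryConditions, FluidProperties, SolverConfig
from .synthetic import SyntheticVesselSpec

DEFAULTS: dict = {
    "vessel": {
        "parent_radius": 2.0,
        "parent_length": 30.0,
        "centerline_curvature": 0.05,
        "sac_radius": 3.0,
        "neck_radius": 1.8,
        "sac_height_offset": 0.0,
        "mesh_edge_target": 0.35,
        "seed": 0,
    },
    "fluid": {
        "density": 1060.0,
        "dynamic_viscosity": 3.5e-3,
    },
    "bc": {
        "systolic_speed": 67.6,
        "diastolic_speed": 26.2,
        "heart_rate": 79.0,
        "inlet_profile": "parabolic",
        "outlet_pressure": 0.0,
    },
    "solver": {
        "steps_per_cycle": 100,
        "n_cycles": 2,
        "target_cell_size": 0.5,
        "convergence_tol": 2e-5,
        "seed": 0,
    },
    "output": {
        "directory": "run",
        "write_vtk": False,
    },
}


class ConfigError(ValueError):
    """One or more schema violations; the message lists all of them."""


def validate_config(config: dict | None) -> dict:
    """Fill defaults, reject unknown keys, and type-check all values.

    Returns the normalized config dict.  An empty/None config yields the
    full default configuration.
    """
    config = config or {}
    errors: list[str] = []
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    normalized = copy.deepcopy(DEFAULTS)
    for section, values in config.items():
        if section not in DEFAULTS:
            errors.append(f"unknown section '{section}'")
            continue
        if not isinstance(values, dict):
            errors.append(f"section '{section}' must be a mapping")
            continue
        for key, val in values.items():
            if key not in DEFAULTS[section]:
                errors.append(f"unknown key '{section}.{key}'")
                continue
            default = DEFAULTS[section][key]
            if isinstance(default, bool):
                if not isinstance(val, bool):
                    errors.append(f"'{section}.{key}' must be a boolean")
                    continue
            elif isinstance(default, (int, float)):
                if isinstance(val, bool) or not isinstance(val, (int, float)):
                    errors.append(f"'{section}.{key}' must be a number")
                    continue
            elif isinstance(default, str) and not isinstance(val, str):
                errors.append(f"'{section}.{key}' must be a string")
                continue
            normalized[section][key] = val

    # semantic checks via the dataclass validators
    if not errors:
        for build, name in (
            (lambda: vessel_spec(normalized).validate(), "vessel"),
            (lambda: fluid_properties(normalized).validate(), "fluid"),
            (lambda: boundary_conditions(normalized).validate(), "bc"),
            (lambda: solver_config(normalized).validate(), "solver"),
        ):
            try:
                build()
            except ValueError as exc:
                errors.append(f"{name}: {exc}")
    if errors:
        raise ConfigError("; ".join(errors))
    return normalized


def load_config(path: str | Path | None) -> dict:
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    return validate_config(raw)


def vessel_spec(cfg: dict) -> SyntheticVesselSpec:
    v = cfg["vessel"]
    return SyntheticVesselSpec(
        parent_radius=v["parent_radius"], parent_length=v["parent_length"],
        centerline_curvature=v["centerline_curvature"],
        sac_radius=v["sac_radius"], neck_radius=v["neck_radius"],
        sac_height_offset=v["sac_height_offset"],
        mesh_edge_target=v["mesh_edge_target"], seed=int(v["seed"]),
    )


def fluid_properties(cfg: dict) -> FluidProperties:
    f = cfg["fluid"]
    return FluidProperties(
        density=f["density"], dynamic_viscosity=f["dynamic_viscosity"]
    )


def boundary_conditions(cfg: dict) -> FlowBoundaryConditions:
    b = cfg["bc"]
    return FlowBoundaryConditions(
        systolic_speed=b["systolic_speed"],
        diastolic_speed=b["diastolic_speed"],
        heart_rate=b["heart_rate"], inlet_profile=b["inlet_profile"],
        outlet_pressure=b["outlet_pressure"],
    )


def solver_config(cfg: dict) -> SolverConfig:
    s = cfg["solver"]
    return SolverConfig(
        steps_per_cycle=int(s["steps_per_cycle"]),
        n_cycles=int(s["n_cycles"]),
        target_cell_size=s["target_cell_size"],
        convergence_tol=s["convergence_tol"], seed=int(s["seed"]),
    )
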