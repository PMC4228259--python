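# aneuflow

Retrospective aneurysm hemodynamics on vascular surface meshes: measure an
aneurysm's morphometry, virtually remove the sac and repair the parent-vessel
wall to its "pre-aneurysm" state, simulate pulsatile blood flow in both
states, and quantify wall shear stress (WSS), its surface gradient (WSSG),
pressure, velocity and the intra-saccular flow-pattern class.

Cerebral aneurysms are believed to form where the arterial wall is exposed to
sustained high WSS, and to evolve under the low-WSS, complex-flow conditions
inside the sac. Prospective imaging of a vessel *before* an aneurysm forms is
rarely available, so the retrospective trick is to reconstruct the
pre-aneurysm artery computationally: excise the sac at its neck and fill the
orifice with a surface patch whose curvature continues the surrounding wall,
then compare hemodynamics before and after. This package implements that
workflow end to end for synthetic sidewall-aneurysm geometries with
analytically known ground truth, which makes every stage testable.

The quantities at the core, in the field's standard notation:

- **D, H, N** — maximum sac diameter, sac height above the neck plane, and
  neck diameter (area-equivalent), in mm, plus the dimensionless ratios
  H/N (aspect ratio), D/H and D/N used as rupture-risk morphometrics.
- **WSS** = tangential component of the viscous traction μ(∇u+∇uᵀ)·n at the
  wall (Pa); **WSSG** = |∇ₛ|WSS|| along the wall surface (Pa/mm).
- Flow is incompressible Newtonian Navier–Stokes (ρ = 1060 kg/m³,
  μ = 3.5 mPa·s), one cardiac cycle at 100 time steps, driven by a
  raised-cosine inlet waveform between the diastolic and systolic Doppler
  speeds; all readouts at peak systole.
- **Cebral types I–IV** — intra-saccular flow taxonomy combining inflow-jet
  direction stability with the number and persistence of vortices; an
  inflow jet or impaction zone is "narrowed" when it spans < 50% of the
  widest sac cross-section.

See `docs/methods.md` for the numerical methods (MINI-stabilized P1/P1
finite elements, monolithic semi-implicit stepping, curvature-variance hole
filling) and the design rationale.

## Worked example

```python
from aneuflow.config import validate_config
from aneuflow.pipeline import run_retrospective

report = run_retrospective({
    "vessel": {"mesh_edge_target": 0.4},
    "solver": {"steps_per_cycle": 50, "n_cycles": 2, "target_cell_size": 0.55},
})
print(report["morphometry"]["rounded"])
print(report["flow_pattern"]["cebral_type"])
print(report["wall_metrics"]["ratios"])
```

On the default study geometry (a 2 mm-radius parent artery with a localized
bend carrying a 3 mm sidewall sac on the outer wall) this prints:

```
{'D': 6.0, 'H': 5.48, 'N': 3.7, 'H_over_N': 1.48, 'D_over_H': 1.09, 'D_over_N': 1.62}
I
{'dome_over_neck_wss': 0.337..., 'dome_over_distal_neck_wss': 0.17...,
 'site_over_adjacent_wss': 1.30..., ...}
```

Reading: the sac measures 6.0 × 5.5 mm over a 3.7 mm neck (aspect ratio
1.48); the intra-saccular flow is type I (stable jet, single vortex); mean
WSS at the dome is ~6× lower than at the distal neck at aneurysm status;
and after virtual repair the formation site carries ~1.3× the WSS of the
adjacent parent artery — the two qualitative signatures of retrospective
aneurysm studies.

The same workflow is scripted step by step under `analysis/`
(01_generate_geometries … 06_classify_patterns), each writing its tables to
`results/`. A command-line entry point is also installed:

```bash
aneuflow synth --out mesh.stl          # synthetic vessel + ground truth
aneuflow measure mesh.stl              # D, H, N and ratios
aneuflow repair mesh.stl --out pre.stl # virtual sac removal
aneuflow retro --out run/              # the full retrospective study
```

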