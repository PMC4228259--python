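#!/usr/bin/env python
"""Build the study geometries: a curved parent artery carrying a sidewall
aneurysm on the outer bend, its sac-free twin, and a hemispherical-sac
control.  Writes STL surfaces plus analytic ground-truth records to
results/geometry/."""

import json
from pathlib import Path

from aneuflow.config import DEFAULTS, vessel_spec
from aneuflow.synthetic import generate_vessel

OUT = Path(__file__).resolve().parent.parent / "results" / "geometry"
OUT.mkdir(parents=True, exist_ok=True)

spec = vessel_spec({"vessel": DEFAULTS["vessel"]})
mesh, truth = generate_vessel(spec)
twin, twin_truth = generate_vessel(spec.without_sac())

import dataclasses
hemi = dataclasses.replace(spec, sac_radius=1.5, neck_radius=1.5,
                           centerline_curvature=0.0)
hemi_mesh, hemi_truth = generate_vessel(hemi)

for name, m, t in (("aneurysm", mesh, truth),
                   ("parent_twin", twin, twin_truth),
                   ("hemisphere_control", hemi_mesh, hemi_truth)):
    m.save(OUT / f"{name}.stl")
    t.save(OUT / f"{name}.truth.json")
    print(f"{name}: {len(m.vertices)} vertices, volume {m.volume():.1f} mm^3,"
          f" watertight={m.is_watertight()}")

summary = {
    "study_case_true_DHN_mm": [truth.D, truth.H, truth.N],
    "hemisphere_true_DHN_mm": [hemi_truth.D, hemi_truth.H, hemi_truth.N],
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))
print("ground-truth D/H/N of the study case:",
      [round(x, 3) for x in summary["study_case_true_DHN_mm"]])
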