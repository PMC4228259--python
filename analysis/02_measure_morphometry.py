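#!/usr/bin/env python
"""Morphometry of the study case plus the two published patients.

Measures D, H, N on the synthetic aneurysm with the full centerline ->
neck-detection -> morphometry chain and compares against the generator's
analytic truth; then recomputes the dimensionless ratios of the two
patients from their printed dimensions.  Writes results/morphometry.json."""

import json
from pathlib import Path

from aneuflow.config import DEFAULTS, vessel_spec
from aneuflow.morphometry import (AneurysmMorphometry, compute_morphometry,
                                  detect_neck, extract_centerline)
from aneuflow.synthetic import generate_vessel

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

spec = vessel_spec({"vessel": DEFAULTS["vessel"]})
mesh, truth = generate_vessel(spec)
cl = extract_centerline(mesh, truth.inlet_center, truth.outlet_center)
neck = detect_neck(mesh, cl)
morph = compute_morphometry(mesh, neck)

print("synthetic case  measured vs true (mm):")
for k, meas, true in (("D", morph.D, truth.D), ("H", morph.H, truth.H),
                      ("N", morph.N, truth.N)):
    print(f"  {k}: {meas:6.2f} vs {true:6.2f}")
print("  ratios:", morph.rounded())

patients = {
    "ruptured": AneurysmMorphometry.from_dimensions(7.20, 10.1, 5.70),
    "unruptured": AneurysmMorphometry.from_dimensions(4.10, 5.0, 5.0),
}
print("\npatient ratio recomputation (2 dp):")
for name, m in patients.items():
    print(f"  {name}: H/N={m.rounded()['H_over_N']}, "
          f"D/H={m.rounded()['D_over_H']}, D/N={m.rounded()['D_over_N']}")

out = {
    "synthetic": {"measured": morph.to_dict(),
                  "true": {"D": truth.D, "H": truth.H, "N": truth.N}},
    "patients": {k: m.rounded() for k, m in patients.items()},
}
(OUT / "morphometry.json").write_text(json.dumps(out, indent=2))
print("\nwrote", OUT / "morphometry.json")
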