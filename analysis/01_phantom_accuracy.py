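#!/usr/bin/env python
"""Phantom mass accuracy: rasterised vs closed-form masses across grid
resolutions, plus the septal-geometry checks (arc fraction, insertion
angles, rotation symmetry).

Writes results/phantom_accuracy.tsv and results/septal_geometry.json.
"""

import json
from pathlib import Path

from cardiomass import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

acc = ex.phantom_accuracy(spacings=(2.0, 1.0, 0.5), n_phantoms=8, seed=0)
acc.to_csv(OUT / "phantom_accuracy.tsv", sep="\t", index=False, float_format="%.6g")

summary = acc.groupby("spacing")[["rel_err_total", "rel_err_apical", "rel_err_septal"]].mean()
print("mean relative error vs analytic truth, by pixel spacing (mm):")
print((100 * summary).round(3).to_string())
fine = acc[acc["spacing"] == 0.5]
print(
    f"\nat 0.5 mm: worst total {100 * fine.rel_err_total.max():.2f}%, "
    f"apical {100 * fine.rel_err_apical.max():.2f}%, "
    f"septal {100 * fine.rel_err_septal.max():.2f}% "
    "(septal limited by the one-pixel insertion-angle resolution)"
)

geo = ex.septal_geometry_check()
(OUT / "septal_geometry.json").write_text(json.dumps(
    {k: v for k, v in geo.items() if k != "rotation_angle_shift_deg"}
    | {"rotation_angle_shift_deg": list(geo["rotation_angle_shift_deg"])}, indent=2))
print(
    f"\n90-deg arc -> septal fraction {100 * geo['septal_fraction']:.2f}% of slice mass; "
    f"insertion angles within {geo['angle_err_deg']:.2f} deg "
    f"(pixel resolution {geo['pixel_angle_deg']:.2f} deg); "
    f"90-deg rotation shifts angles by {geo['rotation_angle_shift_deg'][0]:.0f} deg exactly."
)
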