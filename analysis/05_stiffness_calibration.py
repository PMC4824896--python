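#!/usr/bin/env python
"""Architecture versus stiffness: the equivalent-stiffness control.

Pushes the anterior junk face a uniform 0.1 m caudally and records the
reaction at the posterior constraints for each variant (Model A is
stiffest), then raises the connective-tissue Young's modulus of Models B
and C by bisection until their reactions match Model A's, and re-runs the
ramming comparison.  Expected finding: even at matched overall stiffness,
Model C still concentrates more stress on the anterior skull — the effect
is architectural, not a bulk-stiffness artefact.
"""

from pathlib import Path

import pandas as pd

import whaleram as wr
from whaleram.fem import DEFAULT_MATERIALS
from whaleram.pipeline import regional_summary

OUT = Path("results/05_calibration")
OUT.mkdir(parents=True, exist_ok=True)

meshes = {v: wr.comparison_mesh(v, 0.1) for v in ("A", "B", "C")}
reactions = {
    v: wr.prescribed_displacement_reaction(m, DEFAULT_MATERIALS)
    for v, m in meshes.items()
}
print("posterior reaction under 0.1 m prescribed anterior displacement:")
for v, r in reactions.items():
    print(f"  Model {v}: {r / 1e6:.3f} MN")

rows = []
for variant in ("A", "B", "C"):
    mesh = meshes[variant]
    if variant == "A":
        mult = 1.0
    else:
        mult = wr.calibrate_stiffness(mesh, reactions["A"], tol=1e-6)
    mats = dict(DEFAULT_MATERIALS)
    mats["partition"] = wr.Material(mult * 2.0e9, 0.2)
    mats["case"] = wr.Material(mult * 2.0e9, 0.2)
    lc = wr.make_load_case(mesh, "junk_full")
    bcs = wr.BoundaryConditions.fix_segment(mesh, "posterior")
    u = wr.solve(mesh, mats, bcs, lc)
    stress = wr.recover_stresses(mesh, u, mats)
    reg = regional_summary(stress, mesh)
    rows.append({
        "variant": variant,
        "ct_modulus_multiplier": mult,
        "matched_reaction_MN": wr.prescribed_displacement_reaction(
            mesh, mats) / 1e6,
        "skull_region1_mean_MPa": reg.loc[1, "mean"] / 1e6,
    })

df = pd.DataFrame(rows)
df.to_csv(OUT / "calibrated_comparison.csv", index=False,
          float_format="%.6g")
print()
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
r1 = dict(zip(df.variant, df.skull_region1_mean_MPa))
assert r1["C"] > r1["A"], "ordering must survive stiffness matching"
print("\nregion-1 ordering C > A survives stiffness matching: the "
      "partition effect is architectural")
print(f"outputs under {OUT}/")
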