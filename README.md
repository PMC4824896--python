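# whaleram

Quasi-static finite-element analysis of the sperm whale (*Physeter
macrocephalus*) forehead under ramming loads.

The sperm whale forehead contains two stacked oil-filled sacs: the dorsal
**spermaceti organ** and the ventral **junk**, the latter divided into oil
compartments by near-vertical **connective-tissue partitions** and enclosed
in a fibrous case resting in a trough of the upper jaw. `whaleram` tests,
at desk scale, the battering-ram hypothesis: do the partitions redistribute
impact stress away from the anterior skull?

The pipeline comprises:

* a **parametric 2D head profile** (5.3 m × 1.6 m × 0.1 m slab) in four
  variants — Model A (twelve 0.05 m partitions at 0.150 m spacing), A2
  (tapered partition thicknesses), B (six partitions), C (none) — with a
  conforming structured triangulation;
* a **plane-stress constant-strain-triangle solver** (sparse direct
  factorisation, exact Dirichlet elimination) with tissue properties
  E = 14.8 GPa / ν = 0.1 (skull), 2 GPa / 0.2 (connective tissue),
  1 GPa / 0.49 (oil–wax);
* **quasi-static impact loading**: F = m·v²/(2d) = 764 kN for a 39,000 kg
  whale at 6.26 m/s stopping over 1 m, applied as a uniform traction over a
  choice of anterior load sites, with a 20.56° angle variant;
* **Monte Carlo uncertainty propagation** (tissue stiffnesses ~ Normal with
  10% coefficient of variation) and an element-wise standardised
  mean-difference statistic

  ```
  z_i = (mean_B,i − mean_A,i) / (½ (sd_A,i + sd_B,i))
  ```

  thresholded at the 99th percentile of its paired label-permutation
  distribution (α = 0.01);
* regional skull-stress summaries, percentage-increase tables, load
  sensitivity sweeps and an equivalent-stiffness calibration control.

## Worked example

```python
import whaleram as wr
from whaleram.pipeline import regional_summary

for variant in ("A", "B", "C"):
    sol = wr.solve_variant(variant, target_h=0.1)   # 764 kN on the junk face
    r1 = regional_summary(sol.stress, sol.mesh).loc[1, "mean"]
    print(f"Model {variant}: anterior-skull mean von Mises {r1/1e6:.2f} MPa")
```

prints

```
Model A: anterior-skull mean von Mises 9.41 MPa
Model B: anterior-skull mean von Mises 9.77 MPa
Model C: anterior-skull mean von Mises 10.30 MPa
```

— removing the partitions raises mean anterior-skull stress by ~10% in this
2D profile (Model C vs A), with the anterior partitions carrying the highest
tensile stress (3.5 MPa vs 1.4 MPa for the posterior four). The numbered
drivers under `analysis/` reproduce the full experiment matrix:

| script | what it does |
|---|---|
| `01_build_models.py` | build and mesh the four variants, region inventory |
| `02_baseline_stress.py` | 764 kN ramming solves, regional tables, partition tension |
| `03_load_sensitivity.py` | load-site and load-angle sweep |
| `04_monte_carlo_significance.py` | Monte Carlo populations, z fields, permutation thresholds |
| `05_stiffness_calibration.py` | equivalent-stiffness control via reaction matching |

A thin CLI wraps the same library calls:
`whaleram build-geometry`, `solve`, `compare`, `montecarlo`, `sensitivity`,
`calibrate`.

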