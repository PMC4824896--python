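# Methods

## Model and assumptions

The head is idealised as a thin sagittal slab (5.3 m long, 1.6 m high,
0.1 m wide) in **plane stress** with the slab width as the out-of-plane
thickness: the narrow domain makes the through-width stress negligible, and
all forces entering the 2D solver are per full slab width (newtons, not
N/m). The analysis is **quasi-static and linear elastic**: the impact is a
steady force (kinetic energy over stopping distance), inertia and wave
propagation are ignored, and all tissues are isotropic, homogeneous and
linear. A known artefact of linear elasticity is reproduced deliberately:
the dorsal portions of the connective-tissue partitions resist compression,
which real fibrous tissue would not; no tension-only elements are used.

Tissue properties (Young's modulus, Poisson ratio): skull 14.8 GPa / 0.1;
connective tissue — partitions and the junk case — 2 GPa / 0.2; oil–wax
mixture of the spermaceti organ and junk compartments 1 GPa / 0.49. Skin
and blubber are excluded.

## Parametric geometry

No coordinates exist for the real profile, so each region is a simple
polygon controlled by exposed parameters (`HeadGeometryParams`), and the
conclusions drawn from the model are comparative orderings, not stress
magnitudes. Layout, bottom to top at any rostral station: skull band
(0.35 m nominal, its dorsal surface dipping 30% at mid-rostrum to form the
trough that cradles the junk), ventral case wall (0.05 m), junk interior,
dorsal case wall (0.05 m), spermaceti organ (0.6 m). Caudal of the 5 m
soft-tissue extent the full column is skull (the cranial wall). The junk
interior holds the partitions: trapezoids spanning the band, narrow
ventrally and broad dorsally (default dorsal/ventral width ratio 1.5, mean
width equal to the nominal thickness). The partitioned zone alternates
0.150 m oil compartments and 0.05 m partitions from the anterior junk face:
**the anterior-most partition sits one compartment behind the rammed
face**. With a partition flush at the face the impact loads it in direct
compression, which inverts the tension pattern the junk architecture
produces; anatomically the rammed surface is oil backed by the case, and
the partitions are loaded through the oil. Model A2 tapers the partition
thicknesses linearly 0.08 → 0.02 m (anterior thickest, mean 0.05 m),
mirroring the progressive posterior thinning of the real partitions. Model
B places its six partitions at the even positions of Model A's twelve
(pitch doubled, same 2.4 m zone).

Meshing is a mapped block grid: mandatory grid lines at every partition
wall, interface breakpoint and region boundary, evenly subdivided to the
target element size; layer interfaces carry the row structure. Every cell
therefore lies wholly inside one region — material labels are exact, region
areas are conserved to machine precision, and thin regions (case walls,
partitions) are refined locally to at least one element through their
thickness. Quads are split into counter-clockwise triangle pairs with
alternating diagonals. At the 0.05 m nominal size this yields edge lengths
essentially all within 15–85 mm. Generation is deterministic.

For element-wise cross-variant statistics, all variants are meshed on the
shared Model A grid and differ only in material labels
(`comparison_mesh`); Model B's relabelling coincides exactly with its
standalone geometry.

## Solver

Constant-strain (3-node) triangles; global stiffness assembled per
material group as K = Σ_g E_g·K̂_g with unit-modulus matrices K̂_g, so
Monte Carlo re-solves only rescale and refactorise. Dirichlet constraints
are applied by row/column elimination (exact zeros, clean reaction
recovery: reactions = K·u − f at constrained dofs); the factorisation is
sparse LU (`scipy.sparse.linalg.splu`). Verification: the patch test is
exact to machine precision, the slender-cantilever tip deflection is within
5% of PL³/3EI at 20 elements through the depth, and global equilibrium
holds to 1e-8 relative on every solve (this tolerance is a deliberate
implementation choice rather than a physically derived value).

## Loading

F = m·v²/(2d) with one whale's mass — 39,000 kg at 6.26 m/s over 1 m gives
764 kN — applied as a uniform traction over a labelled anterior segment:
the organ face, the full junk face, or its superior/middle/inferior thirds
(equal thirds by arc length; their anatomical extents are not quantified
anywhere, so equal thirds is the neutral choice).
Angle 0 is the caudally directed horizontal — the compressive
ramming direction — and positive angles tilt the load ventrally (the
20.56° variant is collinear with the anterior partitions). The traction
integral reproduces the total force vector to rounding error.

## Statistics

Each Monte Carlo iteration draws the three group stiffnesses independently
from Normal(E_nominal, 0.10·E_nominal), truncated at zero by resampling
(at 10 standard deviations from zero the truncation never fires in
practice); Poisson ratios are not sampled, matching the "stiffness only"
protocol. Element-wise z = Δmean/(½(sd_A + sd_B)) uses sample (n−1)
standard deviations — the choice is below the method's resolution but is
fixed and documented here. Significance: paired label permutations (each
permutation exchanges the A/B labels of a random subset of iteration
pairs), per-element 99th-percentile threshold, one-sided exceedance,
α = 0.01. When the requested permutations reach the 2^n distinct
relabellings they are enumerated exactly. Elements with zero pooled
standard deviation yield z = 0 (equal means) or ±∞ (flagged, excluded from
thresholding). Permutations are recomputed from sufficient statistics
(mask-by-data matrix products on pooled-mean-centred data), which is exact
and fast. No cross-element multiplicity correction is applied — the
procedure is per element by design.

**Correlation caveat.** Within one population pair, all elements share the
same three sampled moduli per iteration, so null z values are almost
perfectly correlated across elements: any single pair's rejection fraction
is usually 0 and occasionally large, even though each element's marginal
type-I rate is 0.01. The type-I rate is therefore estimated by averaging
the rejection fraction over independent replicate pairs (the acceptance
script uses 150 replicates at the stated per-pair sizes), and the test
suite additionally verifies binomial-level calibration on populations with
independent element histories, where the 0.01 ± binomial band applies
directly.

Whether paired draws should share common random numbers across variants is
left as an explicit choice: populations are generated from independent
seeds by default (`seed` per population), and pairing enters only through
the permutation scheme.

## Regional summaries and calibration

Skull elements are binned by centroid x into five equal-width bands over
the skull's extent (band edges overridable); ties on a shared edge go to
the lower band; empty bands report as missing. Percentage increase is
100·(cmp − ref)/ref with the partitioned model as reference, so positive
values mean stress rises when partitions are absent. The
equivalent-stiffness control pushes the anterior junk face 0.1 m caudally,
records the posterior reaction (Model A stiffest), and bisects the
connective-tissue modulus multiplier (log-spaced bisection, relative
tolerance 1e-6, ≤60 iterations; the response is monotone by linearity)
until Models B/C match Model A's reaction; the anterior-skull ordering
survives the match.

## Desk-scale settings and what they show

Defaults: element size 0.1 m (~2,000–2,500 elements), 100 Monte Carlo
iterations, 1,000 permutations; the publication-scale 0.05 m / 1,000 /
10,000 is a single config change. The generator emulates the geometry's
topology and material contrast, not the scanned anatomical outline, so the
reproducible findings are directional: anterior-skull stress orders
C > B > A (stable across element sizes 0.2/0.1/0.05 m and the A vs A2
thickness variants), anterior partitions carry more tension than posterior
ones, organ impacts spare the skull but load the case, and significant
Model C vs A differences concentrate in the anterior skull. Absolute
stress magnitudes and 3D reaction magnitudes depend on the full solid
anatomy and are out of scope.

## Known limitations

2D plane stress cannot capture lateral oil displacement or the parasagittal
width profile; the quasi-static load ignores energy dissipation and rate
effects; tissues are linear (partitions wrongly resist compression, case
collapse under organ impacts is not modelled); the profile polygons are
schematic. All of these affect magnitudes; the comparative orderings above
are insensitive to them within the tested parameter ranges.
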