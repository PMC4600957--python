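# Methods

This note records how each quantity is defined and estimated, the
defaults that matter, what the synthetic phantoms do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Volumes, phases, units

All analyses operate on a binarized voxel volume with axes `(z, y, x)`
(slice, row, column) and an isotropic voxel size in μm. The single
canonical phase convention is `True` = material, `False` = pore; every
porosity-side quantity is derived from the complement, so a volume and
its phase inversion have porosities summing to exactly 100%.
Binarization is a global threshold, inclusive on the material side
(`intensity ≥ t`), taken as a required parameter: automatic threshold
selection is out of scope, and the choice is recorded in the volume's
provenance string. Region-of-interest extraction converts mm to voxels
by nearest-integer rounding (5 mm at 4.95 μm/voxel → 1010 voxels) and
records the realized extent. Slice stacks are read in plain
lexicographic filename order by default (`s10` before `s2`) for
determinism across filesystems; a natural-sort option orders by
embedded integers.

## Morphometry

**Porosity** is the pore-voxel fraction, counted in integers before a
single division.

**Specific surface BS/TV** is the area of a triangulated iso-surface at
the 0.5 level of the mask divided by total volume. Voxel-face counting
was rejected because it overestimates oblique interfaces by up to ~50%.
Because the volume is not padded before meshing, no surface is
generated where a phase is cut by the ROI boundary, which excludes the
non-interface cut faces. The mask is pre-smoothed with a Gaussian of
σ = 0.8 voxels before meshing: the raw binary iso-surface of a
voxelized sphere overestimates 4πr² by ~9%, while the smoothed mesh is
within ~0.5% and flat interfaces are unchanged. σ is exposed; σ = 0
meshes the raw mask. Phase inversion leaves the measure unchanged up to
the mesh generator's asymmetric handling of ambiguous cells (<0.1%).

**Pore diameter (Po·Diam)** is sphere-fitting local thickness of the
pore phase. The inscribed-sphere radius at voxel `c` is its Euclidean
distance transform value `EDT(c)` (distance to the nearest material
voxel center); a sphere covers every voxel closer than `r + 0.5` to its
center, the half-voxel slack letting spheres reach the interface that
lies between voxel centers. Radii are processed in descending order;
each level marks its coverage by one distance transform from the level's
centers, so the first level to cover a voxel supplies its diameter
`2·r`. With more than `max_levels` (default 64) distinct EDT values the
radii are binned, each bin represented by its smallest member — the
result is then a lower bound with error bounded by the bin width
(well under a voxel in practice); with fewer distinct values the
computation is exact and matches an exhaustive largest-covering-sphere
search (verified voxel for voxel on small volumes). The reported
Po·Diam is the volume-weighted mean (every pore voxel contributes its
local diameter), the convention of standard bone-morphometry software;
the histogram of diameters is always returned so medians or other
summaries can be recomputed. Grid alignment matters at the ±1 voxel
level: a sphere whose analytic center falls between voxel centers loses
coverage in its boundary shell, so phantom validations center solids on
the grid (odd box sides).

## Frontal-plane projection

The volume is collapsed one output row per slice: `fractions[z, x]` is
the number of pore voxels along the projection axis divided by the
depth. The in-slice row axis (`y`) is the default projection direction
and is exposed as a flag, since only "one row per slice" is inherent to
the construction. Integer pore counts are stored alongside the depth,
so the map's mean fraction equals the volumetric porosity fraction as
an exact integer identity, and shuffling voxels within a column leaves
the map unchanged. Rendering uses a piecewise-linear look-up table with
anchors deep blue (0,0,128) at fraction 0, cyan at 1/3, yellow at 2/3,
red (255,0,0) at 1 — a pinned, reproducible blue-to-red ramp. The
image handed to fractal analysis is the grayscale fraction map
(`round(255·fraction)`, half up), not the colorized rendering: texture
measures should see the scalar field, not a color encoding of it.

## Fractal dimension and lacunarity

**Binary box counting**: `N(ε)` is the number of ε-boxes containing
foreground, minimized over four grid offsets (origin plus half-box
shifts, a symmetric set so transposition does not change the counts);
`D_f = −slope` of `log N` vs `log ε`. Box counts equal exhaustive
enumeration on small images. Default sizes are powers of 2 from 2 px to
a quarter of the short side.

**Differential (grayscale) box counting** treats the image as an
intensity surface. Each ε-column receives `max((max−min)/h, 1)` with
box height `h = ε·G/M` (`G` = intensity range, 256 for 8-bit; `M` =
short image side); `D_f` is the slope of `log ΣN` vs `log(1/ε)`. Two
choices differ from the textbook quantized count `ceil((max−min)/h)+1`
and are deliberate: the continuous count, and a default size series
starting at 8 px. On fractional-Brownian surfaces (theoretical
dimension 3 − H) the quantized count's floor terms depress the estimate
by ~0.2 at small boxes; the continuous form recovers H = 0.5 surfaces
to within ~0.1 while still giving exactly 2.0 on constant and ramp
images. A residual negative bias of ≲0.1 remains — box ranges of
Gaussian surfaces grow slightly faster than ε^H at small ε for
extreme-value reasons — and is visible in study values (≈2.1–2.6 on
frontal maps); D_f comparisons across groups are unaffected, absolute
values should be read with this in mind.

**Lacunarity** uses the gliding-box algorithm: an ε×ε window slides
with stride 1 (true gliding box, computed via an integral image), box
mass is the sum of intensities, `λ(ε) = var/mean²`, and the summary λ
is the unweighted mean over sizes with the per-size series always
reported. λ is 0 for constant images, invariant under intensity
scaling, and undefined (signalled, not zeroed) for all-black images.

## Biomechanics

Compression traces of granule stacks are monotone compaction curves: a
concave toe while granules settle, then quasi-linear crushing, stopped
at a load cap (400 N default). **Stiffness** is the steepest
least-squares line over a window spanning 10% of the displacement
range, searched where the load is below 50% of the cap. The steepest
window is *located* on a Savitzky–Golay-smoothed copy of the load
(locally quadratic, span 0.2 mm, exact on polynomial segments) and the
reported slope is then refit on the raw samples of that window —
otherwise measurement noise systematically inflates a maximum taken
over many windows. **Max displacement** is the first crossing of the
cap, linearly interpolated; **work to failure** is the trapezoidal area
from the start of the trace to that crossing. Compaction curves have no
discrete yield or failure event, so integrating from the trace start is
the only well-defined reading of "area under the curve to failure";
this is noted in every result's metadata. In `analyze_curve` the
crossing and the integral are evaluated on the smoothed signal (span
0.05 mm): a noisy signal otherwise crosses the cap early by about 2.5
noise standard deviations. All smoothing is a no-op on noiseless or
coarsely sampled input, so exact results on clean curves are preserved.
Window span, search region and smoothing spans are parameters.

## Statistics

Group comparisons are rank-based throughout: Kruskal–Wallis with
mid-ranks and tie correction (chi-square approximation, df = k−1);
Conover–Inman pairwise follow-up in Conover's t-statistic form,
`t = (R̄_i − R̄_j) / sqrt(S²·(N−1−H)/(N−k)·(1/n_i + 1/n_j))` with
df = N−k; Mann–Whitney U exact (null enumeration) when both samples
have ≤ 8 tie-free observations, tie-corrected normal approximation
otherwise. Significance is α = 0.05; no multiplicity adjustment is
applied beyond the Conover–Inman procedure itself, matching common
practice for this design, with optional Holm adjustment. The study
table reports mean ± SD and n per group; groups with n < 2 are shown
but excluded from tests with a warning. The exact U test's attainable
two-sided levels make its null rejection rate at α = 0.05 about 0.032
for n = 5 vs 5 (8/252), slightly conservative by construction.

## Synthetic phantoms: what they emulate, and what not

* **Analytic solids** (slab, sphere, cylinder) are voxelized by
  center-of-voxel inclusion, so counts are exact integers and closed
  forms (porosity, interface area, thickness) are known.
* **Gaussian-random-field trabecular volumes**: white noise filtered
  with an isotropic Gaussian of sd = correlation length / voxel size,
  thresholded at the exact order statistic of the requested porosity —
  realized porosity is exact to one voxel. The correlation length sets
  the structure scale. These fields reproduce the porosity, surface
  density and pore-size *scales* of cancellous bone but are
  statistically isotropic and Gaussian: they have no plate/rod
  anisotropy, no cortical shell, no marrow-space connectivity
  constraints. Passing tests therefore validate the estimators, not the
  biology.
* **Granule packings**: random sequential addition of equal
  non-overlapping spheres (optionally clipped by the container wall, as
  settled granules are), each carved with random internal cavities of
  ~1/5 the granule diameter until its material fraction reaches
  1 − inner porosity ± 2%. This reproduces inter-granule void geometry
  and the inner-porosity contrast between formulations at the
  statistical level; it does not model sintering necks, granule shape
  irregularity, or the foam-replica void topology.
* **Fractal fixtures**: Sierpinski carpet (dimension log 8/log 3) and
  spectral-synthesis fractional-Brownian surfaces (amplitude
  `f^−(H+1)`, surface dimension 3 − H).
* **Compression curves**: quadratic toe (C1-continuous into the linear
  region), linear region of known slope truncated past the cap,
  Gaussian load noise, 1 μm displacement sampling (a machine sampling
  ~10 Hz at ~0.5 mm/min). Slope, cap-crossing displacement and exact
  noiseless area are returned as ground truth.

All stochastic generators are bit-deterministic given their seed.

## Reference study and problem sizes

The packaged four-group study uses 128³ volumes at 10 μm voxels, n = 3
per group: two trabecular-field groups at porosity 0.691 (high-density
bone-like) and 0.888 (low-density bone-like, correlation length
120 μm), and two granule packings identical in geometry (130 granules
of 240 μm, about 0.19 of the box side — the ratio of a millimeter-scale
granule to a centimeter tube) differing only in inner porosity, 0
versus 0.5, i.e. a two-fold material-mass contrast. These sizes were
chosen so a full study (morphometry with 32 thickness levels, frontal
projection, fractal measures, statistics) runs in a few minutes on one
CPU while preserving the qualitative structure of interest: porosity
ordering low-density bone > porous granules > dense bone > dense
granules, and higher frontal-map lacunarity for the dense-granule
packing than the porous one. Absolute specimen values from physical
bone and proprietary granules are not reproducible from synthetic
volumes and are not targeted.

## Known limitations

* Local thickness is a lower-bound estimator when radius binning is
  active, and sensitive at the ±1 voxel level to grid alignment of
  near-spherical pores.
* The differential box-counting dimension carries a small negative bias
  on Gaussian-like surfaces (see above) and, on small or nearly flat
  maps, can estimate slightly below its theoretical floor of 2.
* The stiffness definition (steepest 10%-span window) is a pragmatic
  operationalization of "initial tangent slope"; on curves with no
  linear region it returns the steepest-window slope, flagged by the
  reported fit window.
* Marching-cubes surface area retains a ~1–2% discretization residual
  on thin structures even after smoothing.
* Statistics assume exchangeable observations within groups; no
  repeated-measures structure is modeled.
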