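# Methods

This note records the models and procedures nucmorph implements, the
parameter choices that matter, what the synthetic phantoms do and do not
emulate, and the numerical decisions taken where the design was open.

## Imaging model and containers

All volumes are 3D scalar grids with axis order (Z, Y, X) and an explicit
per-axis voxel size in µm; every quantity leaving the library is in µm/µm³,
never pixels. Two intensity conventions are distinguished: *absorption*
(optical-CT of hematoxylin-stained cells; higher value = denser chromatin)
and *fluorescence* (confocal DAPI/FISH/antibody channels). Coordinates are
voxel-center based: voxel index i sits at physical position i·voxel_size.
TIFF round-trips store the voxel size and convention as JSON in the
ImageDescription tag, so a re-read file still knows its units; a file with
no unit metadata and no override is an error, never a silent pixel default.

## Segmentation

Cell and nucleus masks come from a deliberately parameter-light recipe:
Gaussian smoothing (sigma in µm, converted per axis so anisotropic grids
behave identically), a threshold, the largest 26-connected component,
morphological closing with a physical-radius ball (default 0.7 µm), and
hole filling. Three choices were calibrated on phantoms with planted truth:

* **Cell threshold — 3-class multi-Otsu (lower cut).** Absorption volumes
  are trimodal (background, cytoplasm, nucleus). Plain 2-class Otsu places
  the cut above the background/cytoplasm edge midpoint and under-segments
  the cell by ~15 % in volume; the lower of the two 3-class thresholds
  lands at the edge midpoint and recovers cell volume within ~1 %.
* **Nucleus threshold — Otsu refined to the class-median midpoint.** Within
  the cell, Otsu is dragged below the cytoplasm/nucleus midpoint by
  smoothed edge-transition voxels and by bright clumps, inflating nuclear
  volume ~4 % (NC ratio error ~7 %). Iterating the threshold to the
  midpoint of the two class *medians* — medians sit on the intensity
  plateaus and ignore both tails — converges to the plateau midpoint and
  brings NC error under 1 % (Dice ≥ 0.997 against generator masks).
* **Smoothing sigma 0.25 µm.** The concavity index depends on the sharp
  rim of surface invaginations, which is a hull-defining feature; 0.5 µm
  smoothing rounds the rim and biases concavity about −6 percentage points
  at a ~20 % planted deficit. 0.25 µm keeps that bias under ~2.5 pp while
  all other recovery properties hold up to additive noise of 10 % of the
  nuclear base intensity.

Nucleus ⊆ cell is enforced by construction; masks are single components
without internal holes; the recipe is exactly equivariant under
axis-aligned 90° rotations and reflections on isotropic grids.

## Morphometry

* **Nuclear volume** = foreground voxel count × voxel volume.
* **NC ratio** = V_n / (V_cell − V_n), the classical karyoplasmic ratio
  with a cytoplasm-only denominator. (A whole-cell denominator is equally
  consistent with values ≤ 0.65; the cytoplasm convention was fixed once.)
* **Concavity index** = 100·(V_hull − V_n)/V_hull with the convex hull
  voxelized on the mask's own grid using voxel-*center* coordinates
  (`convex_hull_image(..., offset_coordinates=False)`). The default
  half-voxel offsets would inflate a digital ball's hull by ~6 % and break
  the "convex bodies score ≈ 0" anchor; with center coordinates a digital
  sphere scores ≤ 2 %, and the operator agrees with a brute-force
  Delaunay point-in-hull oracle within 0.5 pp. The voxel-space hull avoids
  any mesh dependence.
* **Dense clump count**: threshold T = mean + k·σ of intensities inside
  the nucleus (default k = 2 — per-nucleus adaptive, robust to staining
  intensity variation between cells), 26-connected supra-threshold
  components, discarding components below 0.5 µm³. Recovery is exact for
  clump contrast ≥ 1.5 over the nuclear base, center separation ≥ 2 clump
  diameters, and noise up to 10 % of the nuclear base.

All four features are exactly invariant under axis-aligned 90° rotations
and integer translations.

## Relative radial distance and colocalization

The RRD of a locus uses the centroid-ray construction: with c the
geometric centroid of the nucleus mask and s the spot centroid, the ray
from c through s meets the mask boundary at b, and RRD = 1 − ‖s−c‖/‖b−c‖,
so 0 means periphery and 1 means center; for a sphere this is exactly
1 − r/R. The boundary is located sub-voxel: the mask's signed Euclidean
distance field (positive inside) is interpolated trilinearly along the
ray, marched in quarter-voxel steps, and the zero crossing refined by
linear interpolation. A spot within half a voxel of the centroid returns
1 by convention. For non-convex masks the *first* crossing beyond the spot
is used; re-entries of the ray within a short look-ahead are detected and
logged per spot. A distance-transform (shell) normalization would be an
alternative interior parameterization; the ray definition was chosen
because it anchors exactly to the geometric center and the 0/1 endpoints.
Measured accuracy on spherical phantoms (radius ≥ 10 voxels): center and
boundary anchors exact to ≤ 1 voxel/R, interior positions within 0.022 of
1 − r/R, and generator round-trips (place at requested RRD, re-measure)
within 0.05.

Spot detection is Laplacian-of-Gaussian enhancement at the expected spot
scale (default 0.3 µm), thresholded at mean + k·σ (default k = 3) within
the nucleus, with components under 0.05 µm³ discarded and intensity-
weighted centroids; any number of alleles ≥ 0 is supported and each allele
is reported as its own observation. Colocalization is the plain Pearson
correlation of the two channels' voxel intensities over the whole nuclear
mask — no Costes threshold or sub-region, so the statistic is invariant to
affine intensity rescaling of either channel.

## Dose-response model

The four-parameter logistic

    Y = Bottom + (Top − Bottom) / (1 + 10^((LogIC50 − X)·HillSlope)),
    X = log₁₀(dose µM),  IC50 = 10^LogIC50

is fitted by ordinary (unweighted) nonlinear least squares with
multi-start over the Hill-slope sign (p₀: Bottom = min y, Top = max y,
LogIC50 = median X, HillSlope ∈ {−1, +1}); the two starts bracket the
4PL's well-known mirror local minimum. Parameters are reported in
canonical order Top ≥ Bottom, with standard errors from the Jacobian
covariance and a delta-method SE for the IC50. The fit is exactly
scale-equivariant in dose. Note an identifiability caveat measured on
simulations: with the 10-point 3-fold series from 100 µM, an IC50 in the
tens of µM leaves the lower plateau unobserved, and the unconstrained
Bottom then contributes real estimator variance (single-fit IC50 errors up
to ~40 % at 23 µM planted, medians within ~7 %); a series reaching 1 mM
brackets such IC50s and restores per-experiment recovery within 15 %.

Viability normalization is the two-step plate convention: divide by the
mean of cells-alone wells, then by the (step-1) mean of vehicle wells, so
vehicle maps to exactly 1 (100 %).

## Statistics

Group comparisons are two-sided Mann-Whitney U (exact null for n ≤ 20 per
group without ties, otherwise the normal approximation with tie and
continuity corrections; mid-ranks for ties; identical samples short-cut to
p = 1) and two-sample Kolmogorov-Smirnov. Adjusted p-values are Bonferroni
within each comparison's family of four morphometric features — a
conservative choice suited to the small family. Both tests' type-I error
at n = 200/group is calibrated within [0.03, 0.07] at α = 0.05 over 1000
null simulations. Normality is Anderson-Darling for the composite normal
hypothesis: A² with estimated mean/variance, corrected
A* = A²(1 + 0.75/n + 2.25/n²), and the standard piecewise-exponential
p-approximation (verified to 10 decimals against an independent reference
implementation of the same convention). qPCR fold changes use the Pfaffl
ratio E_t^ΔCt_t / E_ref^ΔCt_ref with ΔCt = control − treated and
efficiencies required in (1, 2].

## Synthetic phantoms

Phantoms are built from analytic geometry but every ground truth is
measured from the *emitted voxel masks* (voxel counts, hull deficits,
connected components, re-measured RRDs), so discretization is shared with
the pipeline under test and recovery checks are meaningful at any grid
size.

* **Cell phantom**: ellipsoidal cell (cytoplasm intensity 0.40) containing
  an offset ellipsoidal nucleus (0.80) over background 0.05; dense clumps
  are spheres at contrast 1.8× the nuclear base (default radius 0.6–0.7 µm,
  centers ≥ 2 diameters apart, placed by random sequential sampling with
  restarts); "concave" nuclei are made by boolean subtraction of balls
  centered on the nuclear surface, which yields a measurable hull deficit
  with known truth; additive Gaussian noise.
* **FISH phantom**: DAPI channel from the nucleus mask; FISH spots are
  Gaussian blobs placed on random rays from the centroid at the radial
  fraction that inverts the requested RRD (with a minimum spot separation,
  default 1.5 µm, because arbitrarily close alleles are unresolvable by
  construction); the H3K9ac channel mixes the standardized FISH signal
  with an independent Gaussian random field in the exact proportion that
  targets a requested whole-nucleus Pearson correlation (hit within
  ±0.05). An axial-step option (e.g. 0.25 µm) emulates confocal
  anisotropy.
* **Cohorts** draw nuclear volumes Normal(mean, sd) (truncated), NC
  targets, Poisson clump counts (capped at what the packing constraint can
  place) and an invagination incidence per condition; defaults sit at the
  scale of an adenocarcinoma line under vehicle (mean nuclear volume
  ≈ 672.7 µm³ with population sd 323.9 µm³, i.e. SEM ≈ 22.9 at n = 200;
  NC ≈ 0.65; ≈ 6 clumps).
* **Viability tables** follow the 4PL law on the 10-point, 3-fold dilution
  from 100 µM with 6 replicates/dose and Gaussian noise sd 3 on a 0–100
  scale; **qPCR tables** satisfy Ct = Ct₀ − log_E(template).

Not modelled, hence outside what passing tests demonstrate about real
data: tomographic reconstruction artifacts and streaks, optical
point-spread blurring and axial elongation, stain chemistry and intensity
gradients, touching cells, intra-nuclear texture beyond the two-level
nucleus+clumps model, and chromatic shift between channels. Generation is
bit-reproducible under its seed.

## Problem sizes used in the shipped checks

The validation suite runs cohorts of 8–24 cells per condition on compact
grids (0.5 µm voxels, ~40³–48³) and single full-scale phantoms (0.35 µm,
~47³); the planted-effect study uses 6 conditions × 24 cells across 8
seeds; IC50 recovery uses 20 seeded plates per line; statistical
calibration uses 1000 null simulations at n = 200/group. These sizes were
chosen so the whole suite runs in minutes on a laptop while every
tolerance is met at the stated value; all generators scale to larger
cohorts and grids (e.g. 200 cells/condition at 256³) by configuration
only.

## Known limitations

* Segmentation is single-cell (one cell per volume) and threshold-based;
  it assumes the bimodal/trimodal contrast the stains provide and will not
  split touching cells or handle strong illumination gradients.
* The concavity index quantifies hull deficit only; it does not
  distinguish one deep invagination from several shallow ones.
* The clump count is a texture proxy, sensitive to the k·σ threshold for
  clump contrasts near 1 + kσ/µ; counts, not sizes or positions, are
  reported.
* RRD interiors depend on the chosen ray construction; other published
  radial normalizations (distance-transform shells) coincide at the 0/1
  anchors but differ in between for non-spherical nuclei.
* The 4PL identifiability caveat above applies to any assay whose dose
  range does not bracket the IC50.
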