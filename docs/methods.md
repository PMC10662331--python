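# Methods

## Scope and model

`territoria` quantifies chromosome-territory organization in two-channel
(DAPI + chromosome-paint) confocal images. All analysis runs on 2D maximal
projections: adherent cultured nuclei are only a few microns deep and
territories typically span most of the z range, so projection loses little
and makes segmentation and geometry far more robust at these pixel counts.
3D reconstruction is out of scope.

Image arrays are indexed (row, col) with the origin top-left. Every
user-facing angle is converted once, at the geometry layer, to the
mathematical convention (degrees counter-clockwise from +x in a y-up
frame) and folded to [0°, 180°) where the quantity is an undirected line;
users never see the raster convention.

## Segmentation

Nuclear masks (DAPI): (1) non-local-means smoothing to even out staining
(patch size 3, patch distance 7, filtering strength `h = 0.8·σ̂` with σ̂
the wavelet-based noise estimate; skipped for exactly noiseless input);
(2) Kapur maximum-entropy threshold; (3) morphological closing with a
radius-2 disc (a 2-px dilation followed by a 2-px erosion, undoing
boundary artifacts of the smoothing); (4) connected components (8-
connectivity); (5) discard components larger than 10,000 px (strict) or
touching the image frame, both of which make shape and ring measures
unreliable. A debris floor (default 500 px, `nucleus_min_area_px`,
disableable) suppresses small non-nuclear objects; no lower bound is
inherent to the recipe.

Territory masks (paint): (1) median filter over a radius-2 disc; (2) Kapur
threshold whose histogram is restricted to pixels inside the union of
nuclear masks — the relevant contrast is territory vs intranuclear
background, not vs the dark extracellular field; (3) components with area
in [100, 10,000] px inclusive are kept. Territories are assigned to the
nucleus containing their centroid, falling back to the nucleus holding
≥ 50 % of their pixels; otherwise they are flagged and excluded.

The Kapur threshold is computed from the histogram: the level `t`
maximizing the summed Shannon entropies of the two classes `{≤ t}`,
`{> t}`. Ties (e.g. symmetric histograms) break toward the lower level,
with a 1e-9 tolerance on the criterion so analytically tied levels resolve
identically regardless of float evaluation order. Continuous images are
binned into 256 equal bins over [min, max]. A histogram with fewer than
two occupied bins (constant image) is an error, not a threshold.

Merged adjacent nuclei (e.g. multinucleated myotubes) are deliberately
tolerated as single objects; watershed splitting is a non-goal.

## Morphometry

Axis lengths, area and eccentricity come from the moment-equivalent
ellipse of the binary mask (the CellProfiler convention); axes are
reported as full lengths in microns. Centroids are unweighted mask
centroids. Orientation is computed from the mask's second central moments
in the shared math convention — the same convention the scene generator
uses — so generated and measured orientations compare directly.

Identifiability caveat: near a circle, neither orientation (no major axis)
nor eccentricity (the map `√(1 − (b/a)²)` amplifies a sub-percent
discretization error in the axis ratio to ~0.03 in eccentricity below
ratios of ~1.02) is recoverable to tight tolerance; recovery tests
therefore assert orientation above axis ratio 1.1 and tight eccentricity
above 1.05. Axis lengths themselves recover to < 2 % at all ratios.

## Radial rings

Each nucleus is partitioned into `n_rings = 6` bands of its normalized
distance-to-edge, `ρ = 1 − d_edge/d_edge,max`, where `d_edge` is the
Euclidean distance transform to the nearest background pixel. Ring `k`
holds pixels with `ρ ∈ ((k−1)/6, k/6]`; `ρ = 0` (the innermost pixel) goes
to ring 1. The binning is half-open so the rings partition the mask
exactly and results are bit-reproducible. Equal-width bands of ρ are the
default (the convention of mainstream intensity-distribution modules and
well defined for non-elliptical masks); equal-area rings (ρ-quantile
edges) are available via `rings.mode = equal_area` for sensitivity checks,
and shift absolute ring fractions. Masks too small to populate all six
rings are flagged and excluded from ring statistics.

Per-nucleus outputs: paint-signal fraction per ring (restricted to the
nucleus's territories by default; fractions sum to 1 within 1e-9) and mean
DAPI per ring, raw and normalized to the nuclear mean.

## Density ratio and axial orientation

`R = median(DAPI in territory) / median(DAPI in nucleus)` cancels
staining, illumination and acquisition scale; it is reported per
territory. A zero nuclear median is an error.

The axial angle θ is measured between the undirected major-axis line and
the vector from the nuclear centroid to the territory centroid, folded to
[0°, 180°); the class boundary at 45°/135° is inclusive toward
major-parallel. Per-cell classification uses the diploid scheme
(`both_minor` vs `one_plus_major`, exactly two signals required) or the
aneuploid scheme (`ge50_major` iff at least half the signals are
major-parallel). Nuclei with no retained territory are excluded from
axial and occupancy statistics with a logged reason, as are territories
whose centroid coincides with the nuclear centroid.

## Random-positioning nulls

Three nulls for P(major-parallel) are provided and reported side by side,
since the geometry of "random" is a modelling choice:

- `naive`: 0.5 — the angle itself uniform.
- `ellipse_corrected`: a point uniform in the nuclear ellipse with
  semi-axes `a ≥ b` is major-parallel with probability
  `p = (2/π)·arctan(a/b)`. Derivation: the elliptical sector from polar
  angle 0 to φ has area `(ab/2)·t` with parametric angle
  `t = arctan((a/b)·tan φ)`; the within-45° region is two opposite 90°
  sectors, so `p = 2·ab·arctan(a/b) / (πab)`. This corrects for the longer
  run of the major axis in elongated nuclei; it is strictly increasing in
  `a/b`, equals 0.5 for a circle, and approaches 1 with elongation.
- `empirical_mask`: Monte-Carlo over the segmented mask treated as a
  region (random pixel + uniform in-pixel jitter — pixel centers alone
  systematically over-count the inclusive 45° boundary on the lattice
  diagonals), with a binomial standard error.

Per-cell expected proportions assume the homologs position independently:
P(both_minor) = (1 − p)² for the diploid scheme; a binomial upper tail for
the aneuploid scheme.

## Statistical tests

Observed-vs-expected counts use the exact two-sided binomial test with the
minimum-likelihood tail (sum of P(X = j) over all j with
P(X = j) ≤ P(X = k)); 2×2 comparisons use Fisher's exact test with the
same two-sided convention. Both are computed by direct pmf enumeration
over the support with a 1e-12 relative tie tolerance, and p-values whose
exact value is 1 are snapped from float dust to exactly 1. Group
comparisons of continuous measures use the two-tailed Welch *t* test
(unequal variances, Satterthwaite df). Dispersion is compared by the
coefficient of variation (sample SD / mean). No multiple-testing
correction is applied by default (pairwise tests are reported unadjusted);
a Holm adjustment is available as `holm_adjust`.

Calibration note: the exact binomial test is conservative at finite n —
at n = 100, p₀ = 0.5 its attained size at α = 0.05 is 0.0352 (rejection
region k ≤ 39 or k ≥ 61), so simulated null rejection rates concentrate
near 3.5 %, not 5 %.

## Synthetic scenes

The generator emulates the statistical structure of the target images,
with defaults chosen to match the reported scale of cultured myogenic
nuclei at a pixel size of 0.13 µm/px:

- Nuclei: ellipses, semi-major 44–54 px (full major axis ≈ 12–14 µm),
  axis ratio 1.3–1.7 (eccentricity ≈ 0.64–0.81), uniform orientation, one
  nucleus per frame by default; `multinucleated_specs` lays out several
  nuclei with a configurable edge gap (gap 0 yields tangent ellipses whose
  masks merge, reproducing the multinucleated/adjacent-nuclei case that
  segmentation deliberately treats as one object).
- DAPI: `base + (peak − base)·ρ^exponent` with base 70, peak 115, exponent
  1 — a ~1.6× center-to-periphery rise reproducing the peripheral
  DNA-density pattern while keeping the in-nucleus spread well below the
  nucleus/background contrast (a much steeper gradient would defeat any
  global nucleus threshold, entropy-based or otherwise). Exponent 0
  degenerates to a flat field at `peak` (ρ⁰ ≡ 1).
- Territories: discs of `territory_area_fraction` (default 0.03, ≈ 6 %
  occupancy for the default two homologs) of the nuclear area, clipped to
  the nucleus; paint intensity = `paint_contrast` (default 4) × paint
  background; DAPI multiplied by `dapi_contrast` (default 1.1) inside the
  territory — the ground truth for R.
- Placement: radial position ρ* sampled from a named law (default
  Beta(2.5, 1.5), a peripherally-shifted profile; uniform and fixed are
  available); axial angle from a von Mises distribution on 2θ centred on
  the major axis — axis-symmetric and wrapped, with concentration 0
  *exactly* uniform on [0°, 180°) and `concentration_for_major_fraction`
  solving for the concentration that yields a target major-parallel
  probability. The centroid is found by marching along the sampled
  direction to the sampled ρ; truth rows record both the sampled and the
  realized (post-discretization) ρ, θ and ring index.
- Noise: additive Gaussian (σ default 2) on both channels over constant
  backgrounds (DAPI 5, paint 20), clipped at zero.
- Determinism: per-scene seeds spawn from the master seed; identical seeds
  give byte-identical scenes and truth tables.

What the generator does *not* emulate: PSF blur and optical anisotropy,
chromatic shift, photobleaching, intranuclear texture (nucleoli,
heterochromatin foci), irregular nuclear shapes, and z-structure. Passing
recovery tests therefore validates the measurement chain — geometry,
thresholding behaviour on realistic contrasts, counting, statistics — not
robustness to every property of real micrographs.

## Reference experiments and problem sizes

The packaged experiments (also run by `scripts/acceptance.py`) use:
50 ellipses for morphometry recovery; a 10-scene cohort for ring fidelity;
4 noiseless scenes for density-ratio recovery; 10⁶ Monte-Carlo points per
axis ratio for the null-model cross-check; 1,000 cohorts × 100 angles for
test calibration (sampled directly from the generator's angular law —
by symmetry, downstream measurement noise cannot alter the Bernoulli(½)
class distribution under the uniform null); and 20 end-to-end cohort
replicates of 100 single-territory nuclei (128×128 px frames) for power
(true major fraction 0.75) and false-positive (0.5) rates. These sizes
give stable estimates at interactive runtimes on a single CPU.

## Known limitations

- Merged adjacent nuclei are measured as one object by design; their
  morphometry and ring partitions describe the merged region.
- The 256-bin histogram quantization makes thresholds on continuous
  images reproducible but granular at extreme dynamic ranges.
- The ring definition (equal-width in ρ) affects absolute ring fractions;
  cross-study comparisons should fix the convention.
- The aneuploid per-cell null averages per-cell expected probabilities
  across observed signal counts before the binomial test, which is exact
  only when counts are homogeneous.
- Centroids are unweighted mask centroids throughout the shipped
  statistics; `nucleus_morphometry` accepts an intensity image for a
  weighted centroid in sensitivity analyses, but the pipeline does not
  switch conventions mid-run.
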