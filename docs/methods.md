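# Methods

This note documents the models, algorithms, numerical choices and
limitations of `icmscope`. It is written for users deciding whether the
package's assumptions fit their data, and for maintainers wondering why a
particular design was chosen.

## The measurement problem

Bacteriochlorophyll a autofluorescence is a live-cell proxy for the
intracytoplasmic membrane (ICM) of purple nonsulfur bacteria: its intensity
tracks cellular BChl content, and its spatial pattern along the cell's long
axis distinguishes *longitudinally restricted* localization (discrete foci
at conserved distances from the poles) from *nonrestricted* localization
(signal spanning the cell). The fluorescence pattern does **not** inform on
ICM architecture (lamellar stacks vs vesicles); the package deliberately
stops at axial localization and treats architecture only as a discrete trait
on the species tree.

## Synthetic scenes

`synthetic.generate_scene` is the package's ground-truth source. It models:

- **Cell shape.** Spherocylinders of width *w* (default 0.8 µm) along a
  straight or slightly curved (circular-arc) axis; pole-to-pole length is
  drawn from a truncated normal (default mean 2.2 µm, sd 0.6, bounds
  [1.5, 4.2] µm — chosen as a realistic rod-cell population; the lower bound
  is a plausible newborn-cell size and keeps the conserved focus distance
  d_old = 0.6 µm inside the old-pole half of even the shortest cells, as the
  restricted phenotype requires). Cells longer than *L** taper to 80% width
  toward the new pole, a light-weight stand-in for budding morphology; no
  full budding model is attempted.
- **Localization.** Restricted: an axial Gaussian focus of extent σ_focus
  (default 0.25 µm) centered d_old from the old pole; cells longer than
  *L** (default 2.5 µm) gain a second focus d_new from the new pole at
  ρ × the first focus's peak (ρ ≤ 1; the younger focus is weaker).
  Nonrestricted: uniform in-cell intensity. Intensity depends only on the
  axial coordinate, so the transverse mean used by the profiler is unbiased.
- **Channels.** Phase contrast is rendered as dark cells on a bright
  background; the adhesin channel places a diffraction-limited Gaussian spot
  at the old pole of a random `adhesin_fraction` of cells (only part of a
  real population carries the unipolar adhesin).
- **Optics and noise.** Gaussian PSF (default σ 0.1 µm), then Poisson shot
  noise on the photon-scale image and additive Gaussian read noise (default
  sd 2). Blur uses zero-padding and placement enforces a ≥ 4·σ_PSF border,
  so the total noise-free signal equals the sum of per-cell integrals plus
  background to better than 0.1% (asserted by test).
- **Placement.** Rejection sampling with a 2 px exclusion margin and a
  100-attempt cap per cell; exceeding the cap raises an error naming how
  many cells were placed.

Everything is deterministic given the scene seed (noise streams are derived
sub-seeds). What the generator does **not** emulate: autofluorescent debris
and out-of-focus cells, uneven illumination, phase halos, cell crowding into
microcolonies, time evolution, 3D optics, and spectral structure. Passing
tests therefore demonstrate correctness of the measurement chain under
idealized-but-noisy imaging, not robustness to every real-microscopy
artifact.

## Registration

The optical distortion between phase and fluorescence paths is modeled as a
low-order polynomial (affine by default, quadratic optionally) fitted by
least squares to landmark pairs; the full elastic registration used with
real optics is out of scope, on the grounds that a consistent instrument
distortion is low-order over a field of view. `residual_rms` is the
per-coordinate RMS residual of the fit (so landmark jitter of sd 0.3 px per
coordinate yields residual_rms ≈ 0.3). Resampling into phase coordinates is
bilinear; out-of-field pixels are filled with the channel median and flagged
in a returned mask. Rank-deficient (e.g. collinear) landmark geometry raises
an error rather than returning a garbage fit. Downstream segmentation
refuses fields whose provenance lacks the registration flag unless the
caller explicitly waives it (synthetic scenes are aligned by construction
and carry the flag).

## Segmentation and geometry

Cells are darker than background in phase contrast, so detection thresholds
the inverted, Gaussian-smoothed (σ 1 px) phase channel with Otsu's method
(a fixed threshold is available for synthetic or pre-scaled data). A blank
noise-only field is unimodal and would put Otsu mid-noise; a foreground
fraction above 45% is therefore treated as "no detections". Components pass
area (0.5–8 µm²) and aspect (≥ 1.5) filters; these defaults are this
package's own choices for rod-shaped PNSB at 0.065 µm/px.

**Splitting.** A fused pair of rods shows two connected "ridge bands" in its
distance transform (pixels above 60% of the ridge maximum) separated by the
neck at the contact point; when ≥ 2 such bands lie ≥ `split_min_distance`
apart, marker-based watershed on the negative distance transform divides the
component. A single rod has one connected band and is untouched. Exactly
collinear, fully merged rods produce no neck and are geometrically
indistinguishable from one long cell — no shape-based rule can split them.

**Medial axis.** The mask skeleton is built into an 8-connected graph;
side branches shorter than the cell width are pruned iteratively; the
longest geodesic path is smoothed (moving average, window 5, endpoints
fixed — this removes the diagonal-step zigzag that otherwise inflates arc
length at oblique orientations) and extended along its end tangents to the
sub-pixel mask boundary, defined as the 0.5 level of the bilinearly
interpolated mask and located by bisection. That boundary definition is
exactly invariant to integer translation and symmetric under reflections;
the discrete skeleton itself is *not* exactly 90°-rotation-equivariant, so
rotation invariance of length and width holds to ~1%, not exactly. Length is
the arc length of the final polyline; width is twice the mean distance
transform along interior axis points. On a 40 × 8 px rectangle this
convention yields L ≈ 2.6 µm and width ≈ 0.52 µm at 0.065 µm/px.

## Fluorescence quantification

Background is the median intensity outside all cell masks after a 2 px
dilation — robust, per-field, and preferred here over rolling-ball filtering
because it is simple to reason about and to test. The medial profile samples
the axis every pixel (configurable) and averages bilinearly interpolated
intensities over the transverse chord (9 samples spanning the local cell
half-width from the distance transform, optionally capped). Profiles may go
negative after background subtraction; that is expected noise behavior.

Foci are local maxima of the Gaussian-smoothed profile (σ 0.1 µm) with
prominence ≥ 25% of the smoothed maximum and pairwise separation ≥ 0.5 µm,
at most 3 per cell (the data model needs 1- and 2-focus classes; 3 leaves
headroom without inviting noise peaks). Axial positions are refined as the
intensity-weighted centroid over a ±0.3 µm window, mapped back to 2D through
the axis; the focus "mean intensity" is the background-corrected mean over
the same window. Whether maxima should be 1D (axial) or 2D detections is an
open modeling choice; this package commits to axial maxima with 2D
back-mapping, which matches the demograph representation.

## Polarity

The old pole is called from the adhesin channel: the brightest pixel inside
the cell's 3 px-dilated mask must reach SNR ≥ 5 over the extracellular
background (MAD-based sd) *and* lie within 0.5 µm of a pole; otherwise the
cell stays unassigned (a bright mid-cell spot is rejected by the distance
rule). Both thresholds are this package's defaults, chosen for robust
recovery on synthetic data. Assigned cells are flipped so s = 0 is the old
pole; orientation is an involution. Unassigned cells are kept for non-polar
analyses and excluded from pole-referenced statistics; an optional
bright-end-left fallback orients them by their intensity centroid instead.

## Population statistics

- **Demograph:** profiles resampled to a common bin step, left-aligned at
  the old pole (or centered), rows sorted shortest to longest; per-cell
  max-normalization is available but off by default since raw corrected
  intensity is the more informative display.
- **Tukey outliers:** linear-interpolation quartiles, k = 1.5.
- **Spacing regression:** OLS of inter-focus spacing on length over 2-focus
  cells; a zero-variance response is reported as slope 0 with a flag rather
  than an undefined correlation.
- **Old/new comparison:** in oriented 2-focus cells the smaller-s focus is
  old-pole-proximal; the per-cell new/old intensity ratio is summarized by
  its median plus a Wilcoxon signed-rank statistic on the paired
  differences.
- **BChl content:** always recomputed as A770/OD660, never stored; the
  content–fluorescence association is Pearson's r on raw pairs (a rank
  alternative is a one-liner with scipy if needed).
- **Classification:** per-cell occupancy is the fraction of axial samples at
  ≥ 50% of that cell's profile maximum (a Gaussian focus of sd σ in a cell
  of length L occupies ≈ 2.355 σ / L); a cell is focal at occupancy ≤ 0.5,
  and a population is restricted at focal fraction ≥ 0.8, nonrestricted at
  ≤ 0.2, indeterminate between — or when fewer than 30 analyzable cells
  remain, which sets an explicit insufficient-data flag.

All classification labels, ratios and µm-scale regression coefficients are
invariant to a global intensity gain (asserted by test).

## Trait mapping

The species tree is consumed as input (tree inference is out of scope);
Newick I/O is delegated to dendropy with duplicate-leaf and parse checks on
top. Ancestral reconstruction is minimum-change (Fitch) parsimony with equal
costs; internally the engine computes exact per-node minimum-change cost
vectors (unit-cost dynamic programming over states), which generalizes the
classic intersection/union pass to multifurcating trees without forcing a
binary resolution — published trees contain polytomies and the curated
fixture deliberately encodes uncertain placements as polytomies rather than
guessing an order. State sets reported per node are the states achieving the
subtree minimum (identical to Fitch downpass sets on binary trees).
Maximum-parsimony labelings are enumerated by backtracking (capped at 2·10⁵)
to answer set questions such as "does some MP labeling put a nonrestricted
state at the root with every gain of the restricted state inside one
clade?"; ACCTRAN/DELTRAN-style single labelings are provided via tie-break
preferences (change early vs late) with lexicographic determinism. Weighted
(Sankoff) cost matrices are out of scope.

The shipped tree and trait table under `src/icmscope/data/` are
artifact-curated encodings (order-level clades with polytomies, 14 species
plus an outgroup that carries no trait state and exercises the exclude
policy); they are this package's own transcription, not a deposited file.

## Pipeline and reproducibility

`analyze_field` chains segmentation → background → profiling → polarity →
orientation → focus detection; `run` drives it from a validated YAML config,
writes cells/foci/polarity/profiles CSVs, demograph and centroid-map
CSV+PNG, a JSON summary and a manifest (config hash, package version,
per-stage counts). Runs are deterministic given inputs, config and seed;
repeated runs produce byte-identical CSVs. Any stage error aborts with the
stage and offending cell named; exit codes are 0/2/3 for
success/config/data errors.

## Benchmark problem sizes

The built-in benchmarks (`icmscope.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) use: one 300-cell
restricted field (2048² px) for parameter recovery; 10 + 10 populations of
200 cells (1664² px) for classification; one 120-cell field for segmentation
scoring; five 60-cell scenes for the content correlation; 100 random trees
(≤ 8 leaves, ≤ 3 states) against the exhaustive-enumeration oracle; and 20
landmark pairs for registration recovery. These sizes give stable statistics
(hundreds of foci, tens of spacing pairs) while keeping a full run to a few
minutes on one CPU.

## Known limitations

- Segmentation assumes phase-dark, rod-shaped, non-overlapping cells;
  crossing cells and true collinear end-to-end contacts are not separable.
- The medial-axis convention extends to the mask boundary, so lengths on
  flat-ended (cut) shapes include the half-width overhang.
- Focus detection is 1D along the axis; two foci at the same axial position
  but different transverse positions would merge.
- The classifier's occupancy thresholds were designed around the two
  phenotypes the generator renders; intermediate real phenotypes (e.g.
  irregular patchiness) will land in `indeterminate`.
- Parsimony treats all state changes as equal cost and reports sets of
  equally parsimonious answers rather than probabilities; no branch-length
  information is used.
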