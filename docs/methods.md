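# Methods

This note documents the models, conventions and numerical choices behind
`utriclemap`, in the order the pipeline runs them.

## The biological model

The larval zebrafish utricle is treated as a 2D point pattern: one
centroid per segmented hair cell in a maximum-intensity projection, with
two FISH channel intensities per cell.  The organ is assumed to be
approximately elliptical, with a mediolateral zonal split whose boundary
runs along the ellipse's major (anterior–posterior) axis: medial
extrastriolar cells express *cabp1b*, lateral striolar cells express
*cabp2b*, and a narrow band at the boundary contains "intermediate"
cells positive for both.  The pipeline makes no assumption about
absolute staining intensity — only that within one organ and channel,
positive cells are separated from background by a gap that a two-class
natural-breaks partition can find.

## Synthetic utricles

The generator exists so classification, geometry and statistics can be
validated against ground truth.  It emulates:

- **Outline and placement** — a rotated, translated ellipse (defaults
  110 × 70 px, matching a ~200 µm organ at typical magnification);
  centroids are a hard-core (rejection-sampled Poisson-disk) process
  with minimum spacing 2.2 × cell radius, which guarantees disjoint
  rendered masks like segmented nuclei.  At the default 73 cells per
  organ (the study's mean count is ~73) this packs to about half the
  jamming density; substantially larger counts at the same geometry will
  fail with an explicit error rather than overlap.
- **Zones** — a cell's true type comes from its signed distance v to the
  major axis: medial (v > 0) extrastriolar, lateral striolar, and
  intermediate within the boundary band.  `boundary_band_frac` is the
  band width as a fraction of the semi-minor axis b (half-width
  frac·b/2).  For uniform placement the expected intermediate share is
  (2/π)(asin(f/2) + (f/2)√(1−f²/4)) ≈ 2f/π; the default f = 0.08 gives
  ≈ 5%, bracketing the observed 4% wild-type share with 49/47% in the
  two zones.
- **Intensities** — log-normal per cell with configured arithmetic mean
  and CV (defaults 5000 vs 500 image units, CV 0.2): strictly positive
  and right-skewed, like per-cell aggregates of FISH puncta.  Positive
  cells are bright on their zone's channel(s), everything else sits at
  background.  No published intensity distributions exist for these
  probes; these are stated assumptions, not fits.
- **Early-born cohort** — emulating photoconversion birth-dating, a
  fraction of cells is flagged early-born, allocated so the medial share
  equals `early_born_medial_bias` (default 0.81, echoing the observed
  132/163).
- **Ear side** — `mirror` reflects the organ to exercise left/right
  orientation resolution.

Rendering rasterizes each cell as a filled disk carrying its integer
label, with per-pixel Gaussian noise on the channel images.  What the
generator does **not** emulate: 3D curvature of the epithelium, optics
(PSF, chromatic shift), segmentation errors, cell-size variation,
intensity gradients across the organ, and spatial intensity correlation.
Passing tests therefore demonstrate the pipeline's correctness on
cleanly segmented, well-separated data — not robustness to segmentation
failure or marginal staining.

## Classification

Per-cell intensity is the mean (default) or sum over the cell's labelled
pixels; the mean is default because it is insensitive to segmented-area
variation.  Thresholds are computed independently per channel and per
organ, since FISH staining intensity varies between specimens.  The
2-class Fisher–Jenks partition is found by exact dynamic programming
over the sorted values (O(kn²) with prefix sums — exact, not the
heuristic k-means relaxation).  The returned break is the **midpoint of
the gap** between the optimal lower and upper classes, and `value ≥
break` is positive (ties positive).  Class count is fixed at 2
(positive/background).  Degenerate inputs (fewer distinct values than
classes) raise instead of guessing.  Double-negative cells are retained
in outputs but excluded from zonal statistics, matching the three
reported categories.

## Canonical frame

1. **Center**: arithmetic mean of centroids (a convex combination, hence
   always inside the convex hull); the hull-polygon area centroid is
   available as an option.
2. **Concave hull**: k-nearest-neighbour gift wrapping (start at the
   point farthest from the centroid, always on the convex hull; at each
   step take the largest right-hand turn among the k nearest unused
   points that does not self-intersect), escalating k until a simple
   polygon contains every point, with the convex hull as the k ≥ n−1
   fallback.  Two details make the traversal equivariant: the start
   vertex and initial heading are defined relative to the cloud itself
   (not the axes), so the hull commutes with rotation, translation and
   scaling; and the point set is first reflected to a canonical
   chirality — the sign of Hu's skew-sensitive third-order moment
   invariant — and the hull reflected back, so mirrored inputs yield
   exactly mirrored hulls.
3. **Ellipse**: direct least-squares conic fit with ellipse constraint
   to the hull vertices (the hull tracks the organ outline; fitting all
   centroids would weight the interior).  Axes are ordered a ≥ b and the
   major-axis angle reduced to [0, π).
4. **Orientation**: after rotating the major axis onto the x-axis, two
   flips remain undetermined.  The flip across the major axis is
   resolved by marker majority — most extrastriolar-marker-positive
   cells must land in θ ∈ (180°, 360°) — which also absorbs ear side.
   The flip along the major axis (anterior–posterior) has no marker to
   anchor it, so it is resolved by a deterministic data-dependent rule:
   the third moment of the x-coordinates is made non-negative.  Any
   similarity transform of the input then reproduces the canonical frame
   to < 1e-6 (measured ~1e-13).  Images with no marker-positive cells
   require explicit flip flags.
5. **Unit-circle radius**: r = ‖p‖ / d(θ), where d(θ) is the distance
   from the origin to the convex-hull boundary along the cell's ray
   (shapely ray–polygon intersection); r is clipped to [0, 1] against
   float round-off at hull vertices.

## Statistics

- **Binomial sector tests**: exact, two-sided by the minimum-likelihood
  rule (sum of all outcome probabilities ≤ that of the observed
  outcome), the convention of `scipy.stats.binomtest`.  Sectors are
  half-open degree intervals; the boundary sector is the quarter of the
  disk within ±22.5° of the 0°/180° axis, with a 25% uniform null.  No
  multiple-testing correction is applied to sector tests; raw p-values
  are reported at α = 0.05.
- **Two-proportion z**: pooled standard error, no continuity
  correction (`statsmodels proportions_ztest`); all seven published z
  statistics reproduce within ±0.1 under this form.
- **χ²**: Pearson, no Yates correction; goodness-of-fit variants carry
  Cohen's w = √(χ²/N).
- **Effect sizes**: Cohen's d on the pooled SD; bias-corrected Hedges'
  g = d·(1 − 3/(4(n₁+n₂) − 9)) whenever the smaller group has n < 15.
- **Join counts**: the weights graph is the union-symmetrized k-nearest-
  neighbour graph (k = 7, the smallest leaving no unattached cells at
  these densities) over positions — normalized coordinates in the
  pipeline, so graphs are comparable across conditions.  All unordered
  label-pair counts are reported (their sum is |E| by construction); no
  composite statistic is imposed.  Significance uses sampled label
  permutations with the add-one convention, pseudo-p = (1 + #extreme) /
  (n_perm + 1), default 9999 permutations, seeded.
- **KDE**: `scipy.stats.gaussian_kde` on Cartesian unit-disk coordinates
  (matching how polar summary plots are drawn, rather than a circular
  kernel on angles), Scott's bandwidth rule by default.  Densities are
  normalized over the plane; mass outside the disk is not renormalized.

## Problem sizes

The test suite and the acceptance script work at the scale of the study
itself: organs of ~73 cells, cohorts of 10–21 organs (≈700–1500 pooled
cells), 20-seed recovery benchmarks, 2000-replicate calibration of the
sector test (pooled cohorts of 730 cells per replicate, mirroring the
703-cell pooled sample), and 9999-permutation join-count nulls.  The
full suite runs in well under a minute on one CPU.

## Known limitations

- The canonical frame's anterior–posterior resolution is a convention
  (x-skewness sign), not anatomy; organs whose cell cloud is almost
  exactly symmetric along the major axis could resolve either way under
  perturbation.
- Natural-breaks thresholding assumes a bimodal intensity distribution
  per channel; organs with no positive cells on a channel will still be
  split somewhere.  Inspect thresholds (they are recorded per organ) on
  marginal stains.
- The unit-circle normalization uses the convex hull as the boundary, so
  concave indentations of a real organ outline compress radii locally.
- Join-count pseudo p-values are one-sided per pair; deficits (e.g.
  fewer cross-zone joins than chance) are tested with the mirrored
  "lesser" alternative.
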