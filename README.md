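# utriclemap

Zonal classification and spatial statistics of hair cells in the larval
zebrafish utricle.

The utricle, the otolith organ that senses linear acceleration and
gravity, is an oval sensory epithelium split into two zones: a medial
**extrastriola** (hair cells expressing *cabp1b*) and a lateral
**striola** (*cabp2b*), with a thin band of double-positive
"intermediate" hair cells along the zonal boundary.  Comparing this
spatial pattern across animals, ages, drug treatments and mutants
requires (i) calling each segmented cell's type from its FISH marker
intensities and (ii) mapping every organ — imaged at an arbitrary
position, rotation, scale and ear side — into one common reference frame.
This package implements that pipeline for people analyzing segmented
microscopy of vestibular epithelia, together with the statistics used to
compare conditions and a ground-truthed synthetic-utricle generator so
the whole chain is testable without microscope data.

## What it computes

**Classification.**  Per-cell intensity (mean or sum over the cell's
pixels, from an integer label image) is thresholded per channel and per
organ at the 2-class Fisher–Jenks natural break — the split of the sorted
values minimizing the within-class sum of squared deviations; the
returned break is the midpoint of the between-class gap and `value ≥
break` is called positive.  The two marker calls give the type:
*cabp1b*⁺ only → extrastriolar, *cabp2b*⁺ only → striolar, both →
intermediate, neither → negative.

**Canonical frame.**  Cell centroids are recentered on their mean, a
concave hull (k-nearest-neighbour gift wrapping, k escalating until the
polygon contains every cell) outlines the organ, a direct least-squares
ellipse fit to the hull gives the organ's axes, and the point cloud is
rotated so the major axis becomes the 0°–180° line.  The residual flips
are resolved deterministically (marker majority puts the extrastriola in
θ ∈ (180°, 360°)), and each cell's radius is divided by the distance to
the convex-hull boundary along its ray:

    r = ‖p‖ / d_hull(θ),   r ∈ [0, 1],  θ ∈ [0°, 360°)

so every organ lands on the unit disk with the zonal boundary on the
horizontal axis.  The frame is invariant (< 1e-6) to rotation,
translation, uniform scaling and mirroring of the input.

**Statistics.**  Sector occupancy is tested with the exact two-sided
binomial test (e.g. medial half vs 50%, boundary quarter vs 25%);
conditions are compared with the pooled two-proportion z-test
z = (p̂₁ − p̂₂) / √(p̂(1−p̂)(1/n₁ + 1/n₂)) and Pearson χ²; effect sizes
follow the n-rule (bias-corrected Hedges' g for n < 15, Cohen's d
otherwise, Cohen's w = √(χ²/N) for goodness of fit).  Spatial structure
is measured by join counts on a symmetric k = 7 nearest-neighbour graph
with a 9999-permutation null (add-one pseudo p-values), and zone
occupancy maps are 2D Gaussian KDEs (Scott bandwidth) on the unit disk.

## Worked example

```python
from utriclemap import (SimParams, generate_dataset, classify_cells,
                        normalize_organ, sector_fraction, binom_test,
                        two_prop_z, MEDIAL_HALF)

table, _ = generate_dataset(SimParams(seed=7, rotation_deg=37.0))
classified = classify_cells(table)              # Jenks calls + types
normalized, geom = normalize_organ(classified)  # canonical unit disk

es = normalized[normalized["type"] == "extrastriolar"]
k, n = sector_fraction(es["theta_deg"], MEDIAL_HALF)
print(k, n, binom_test(k, n, 0.5).p_value)
# 37 37 1.4551915228366852e-11

z = two_prop_z(159, 265, 302, 346)              # printed treated-vs-control counts
print(round(z.statistic, 2), z.p_value < 1e-4)
# -7.77 True
```

All 37 of this organ's extrastriolar cells fall in the medial half of the
canonical plot — under a fair-coin null that has probability ≈ 1.5e-11,
so the zonal pattern is (correctly) detected as highly non-random.  The
z-test reproduces the published comparison of retinoic-acid-treated vs
control utricles (printed as z = −7.7): treatment scatters *cabp1b*⁺
cells out of the medial half (60% vs 87%).

The `analysis/` scripts run the same stages as a narrative over a
simulated multi-organ cohort (`01_simulate_cohorts.py` …
`06_kde_maps.py`), writing tables under `results/`.  A `utriclemap` CLI
exposes each stage (`simulate`, `classify`, `normalize`, `stats`,
`autocorr`, `kde`, `pipeline`).

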