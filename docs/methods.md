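# Methods

`lianasep` classifies every return of a terrestrial-laser-scanning (TLS)
point cloud of a forest plot as **liana wood** (class 1) or **anything
else** (class 2 — tree wood, foliage, ground, noise), and then corrects
the classifier's characteristic errors with a density-based
post-processing chain. This note records the model, its assumptions, the
numerical conventions, and what the synthetic benchmark does and does not
demonstrate.

## The classification model

Lianas (woody climbers) are thin — stem diameters almost all below 10 cm —
long, non-self-supporting, and loop through the plot in irregular
trajectories. Locally, a liana stem therefore looks like a 1-D filament at
a range of spatial scales, while tree boles look planar-to-cylindrical at
small scales, foliage looks isotropic, and ground looks planar.

The predictor of point *i* is built from the eigenvalues of the 3×3
covariance matrix of all points within radius *r* of *i* (the point itself
included, closed ball). Eigenvalues are sorted descending and divided by
their sum, giving a triple (λ1, λ2, λ3) on the 2-simplex:

- λ1 ≈ 1: linear neighborhood (stem-like),
- λ1 ≈ λ2 ≈ 0.5: planar (ground, large bole surface),
- λ1 ≈ λ2 ≈ λ3 ≈ 1/3: isotropic (foliage).

Concatenating the triples over the radii **0.1, 0.25, 0.5, 0.75 and
1.0 m** gives the 15-dimensional feature vector. Multi-scale
concatenation replaces any optimal-scale selection: a thin branch may be
linear at 0.25 m but not at 1 m, and the forest sees all scales at once.
Radii below 0.1 m are avoided because the cloud is voxel-downsampled to
0.04 m and such neighborhoods would often be nearly empty; radii above
1 m are avoided for memory.

A **random forest** (default 50 trees, all 15 features available at each
split, seeded) is trained on labeled plots. Class imbalance — liana points
are typically 2–9% of a plot — is handled by randomly retaining **10% of
the majority class** (all minority points are always kept). The class-1
probability of a point is the fraction of trees voting class 1; the
default hard-label threshold is 0.5.

Hyperparameters are explored over a 10×7 grid (10, 20, … 100 trees ×
2–8 features per split) scored by mean F1 over spatially disjoint folds.
In practice the score surface is nearly flat, which is why the final
defaults favor the simplest stable setting.

### Spatial cross-validation

Because TLS returns are strongly spatially autocorrelated, folds are
spatially disjoint **sub-areas**, not random point subsets:

- *self-site*: either each plot's 2×2 quadrants validated one at a time
  (eight folds for two square plots), or leave-one-plot-out;
- *cross-site*: train on all plots of one site, validate on the other
  (two folds);
- *mixed-site*: plots of one site subdivided (default 2×3), fold *j*
  validating sub-area *j* of each subdivided plot plus whole plot *j* of
  the other site.

Fold metrics are aggregated as arithmetic mean ± sd; consequently the
mean F1 is *not* the harmonic mean of mean precision and mean recall.
The majority under-sample is re-drawn inside each fold from that fold's
training indices only.

### Evaluation

With class 1 positive: precision TP/(TP+FP), recall TP/(TP+FN), F1 their
harmonic mean, FPR FP/(FP+TN). The precision–recall curve is evaluated at
every distinct predicted probability (descending; predict positive at
prob ≥ t), and average precision is the recall-increment-weighted sum of
precision, AP = Σ_k (R_k − R_{k−1}) P_k with R_0 = 0, computed with
integer TP increments so a perfect ranking gives exactly 1. ROC/AUC and
accuracy are deliberately absent: at 2–9% prevalence they flatter the
majority class. Zero-denominator metrics are reported as 0 and flagged in
the report's `undefined` list.

## Post-processing

The raw model is conservative: precision is high, recall low, because
thick straight liana sections resemble tree wood. The correction chain:

1. **SOR** on the predicted class-1 points (k = 6 neighbors, threshold
   mean + 1.0 sd of the mean-neighbor-distance distribution, strict `>`):
   drops isolated ghost false positives.
2. **Mask** (optional): a scriptable index-list or axis-aligned-box file
   standing in for interactive polygon removal of obvious tree segments.
3. **DBSCAN** (ε = 0.05 m, minPts = 5, counting the point itself) over
   all predicted class-2 points.
4. Every class-2 cluster whose minimum point-to-point distance to a
   cluster of the corrected liana points is ≤ ε is relabelled class 1
   ("close enough that DBSCAN would merge them"). DBSCAN noise points are
   never recovered.

ε = 0.05 m is tied to the 0.04 m point spacing: immediate neighbors along
a surface connect, second neighbors do not. The known failure mode is a
missed liana section lying within ε of other vegetation: it either stays
missed (if its cluster also touches nothing liana) or, worse, drags that
vegetation in; the generator's clearance constraint (below) keeps the
synthetic benchmark out of this regime, as real plots at this spacing
mostly are.

## Numerical conventions

- **Voxel filter**: grid cells are integer multiples of the voxel size
  (the cell containing the cloud's minimum corner anchors the
  enumeration). This lattice convention makes the filter idempotent,
  which a literal min-corner anchor would not be. The retained point is
  the *input point* nearest the centroid of its cell's points — never a
  synthesized centroid — so label/probability columns stay attached to
  real returns.
- **Covariance**: population divisor (1/M); the divisor cancels under
  eigenvalue normalization but is fixed for oracle parity. Moment sums
  are taken about the query chunk's centroid to avoid cancellation far
  from the origin. Neighborhoods with fewer than 3 points or zero total
  variance are degenerate: they get the neutral triple (1/3, 1/3, 1/3)
  and a `valid_mask=False` flag; such points are kept for training by
  default (they are real returns) but can be dropped.
- **SOR** uses strict `>` at the threshold so a zero-variance lattice is
  left intact; neighbor distances are 3-D Euclidean, self excluded.
- **DBSCAN** border points reachable from several clusters go to the
  first cluster reached in the index-ordered scan (deterministic).
- **Feature extraction** is chunked (default 2048 query points per
  chunk) to bound the memory of the neighbor-list expansion; results are
  exact regardless of chunk size.
- All randomness (under-sampling, forest, scene generation,
  perturbations) flows from explicit integer seeds; identical seeds and
  inputs reproduce outputs byte for byte.

## The synthetic benchmark

Field TLS with per-point liana labels is scarce (labelling a single
campaign took the original analysts ~120 hours), so the package ships a
generator that emulates the *geometric contrasts and the class imbalance*
the method exploits:

- trees: vertical tapered cylinders (DBH 0.15–0.60 m, height 5–8 m,
  tip radius 40% of base), area-uniformly sampled;
- foliage: isotropic Gaussian blobs (radius 0.35 m, truncated at 2σ) in
  the upper third of each crown;
- lianas: thin tubes (diameter 0.01–0.08 m) following either a helix
  around a host tree or a looping 3-D spline that dips toward the ground
  and re-ascends;
- a flat ground layer, and a few dozen uniform ghost returns;
- all surfaces sampled at ≈0.04 m spacing with 5 mm Gaussian jitter
  (ranging noise of a survey-grade scanner after voxel thinning).

The default plot is 6 × 6 m with 4 trees and 3 lianas, ≈40–50 k points
after downsampling and a liana fraction of ≈3–4% — inside the 2–9% range
of real plots. This desk-scale default keeps the five-plot
cross-validated benchmark (≈180 k points) a few-minute computation on a
single core; larger plots change the cost, not the structure.

Lianas keep a 0.10 m standoff from host bark and ≥0.25 m ground
clearance. Real lianas can press against bark; at the post-processing ε
this contact regime is exactly the documented failure mode above, and
the generator deliberately stays out of it so that the benchmark
measures the mechanism rather than its known limit.

**What passing the benchmark shows**: that the features separate
filament-like from planar/isotropic/cylindrical geometry, that the
spatially cross-validated forest recovers the liana class well above the
skill floor, and that the correction chain recovers contiguous missed
segments without sacrificing precision. **What it does not show**:
performance under occlusion, variable beam footprint, co-registration
error, bark-contact lianas, liana tangles inside crowns, or mislabelled
training data — all present in real plots, which is why field numbers
are substantially harder than synthetic ones.

`perturb_labels` builds controlled prediction fixtures by flipping a
contiguous arclength window of each liana to class 2 (the "thick straight
stem" miss) and flipping isolated ghost points to class 1; the
post-processing benchmark (recall gain ≥ 0.10 at ≤ 0.02 precision cost)
runs on these fixtures, where ground truth for every correction is known
by construction.

## Known limitations

- LAS support is minimal by design: version 1.2, point format 0, with
  the classification byte carrying the {1, 2} label; probabilities do
  not survive a LAS round trip (use PLY).
- The voxel filter's lattice anchor means a rigid translation of a cloud
  can change which points are retained (the partition is
  translation-covariant, not invariant).
- `recover_false_negatives` clusters *all* predicted class-2 points.
  On plots whose background forms one giant connected component at ε
  this is safe (the component touches no liana cluster at the standoff
  assumption) but costs one DBSCAN run over the majority class.
- The generator does not model occlusion, beam divergence or multi-scan
  registration; its point spacing is uniform by construction.
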