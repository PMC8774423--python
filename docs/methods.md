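# Methods

This note documents the models, parameter choices and numerical conventions
behind `nucleiclust`, and what the synthetic fixtures do and do not show.

## Stain model

**Normalization.** Color transfer runs in CIE LAB (D65, scikit-image's
convention; the white point is recorded here because LAB conversions are not
interchangeable across conventions). Per channel,

    out = (x − μ_src) · (σ_ref / σ_src) + (x + μ_ref) / 2.

This is a *modified* Reinhard transfer: the final term averages the pixel
value with the reference mean instead of substituting the reference mean.
Two consequences users should know about: (a) normalizing an image against
its own statistics is **not** the identity map, unlike classical Reinhard;
(b) the output channel mean lands at (μ_src + μ_ref)/2 rather than μ_ref.
The transform is applied exactly as written; out-of-gamut LAB values are
clipped on conversion back to RGB, not rescaled, so the printed arithmetic
is preserved for in-gamut pixels. A constant source channel makes the
rescaling undefined and raises an error.

**Optical density and deconvolution.** OD = −log10(clamp(I, 1, 255)/255).
The log base is a unit convention only (concentrations rescale uniformly
under a change of base); base 10 is the standard optical-density choice, and
the Beer–Lambert reconstruction I = 255·10^(−c·M) uses the same base so
round trips close. Intensities are clamped to ≥ 1 before the log so a black
pixel has finite OD (≈ 2.4065). The H&E stain matrix is a fixed constant
(rows `[0.587, 0.754, 0.294]` and `[0.136, 0.833, 0.536]`, near unit norm);
estimating stain vectors from images is out of scope. "Dividing" a 3-vector
OD by a 2×3 stain matrix is realized as least-squares projection onto the
two stain color vectors (the only well-defined reading, and standard
color-deconvolution practice); negative concentrations, which arise for
pixels outside the stain cone, are clipped to 0 before re-rendering. For
pixels whose OD lies exactly in the stain plane the projection is the
identity and the round trip is exact up to 8-bit rounding; for quantized
pixels the projection can redistribute up to one quantization step across
channels, amplified by channel intensity ratios, so the ±1 gray-level
closure guarantee is stated for in-plane pixels.

## Segmentation

The hematoxylin single-stain image is converted to classical HSI
(I = (R+G+B)/3, S = 1 − 3·min/sum, H angular); the saturation channel is
used because near-white background has S ≈ 0 while chromatin is strongly
saturated — the nuclei are the bright structures, fixing the foreground
polarity of the threshold. Defaults, all configurable:

| parameter | default | rationale |
|---|---|---|
| contrast stretch | 1st–99th percentile → [0, 255] | robust to single-pixel outliers |
| threshold | Otsu | the standard parameter-free global method |
| watershed markers | distance-transform maxima, min separation 7 px | separates nuclei whose centers are ≥ 7 px apart |
| min object area | 30 px² | below any plausible nucleus at this magnification |
| structuring element | disc, radius 2 px | smooths boundaries without erasing small nuclei |

Small objects are removed both before and after the watershed. The
closing-then-opening cleanup runs per object inside a padded bounding box so
adjacent nuclei cannot merge. Components too small to seed a marker keep a
single label, so labels always partition the thresholded foreground. The
whole pipeline is deterministic for a fixed input and configuration;
coordinates are (row, col), 0-based, pixel centers.

## MST cluster analysis

The complete Euclidean graph over nucleus centroids is reduced to a minimum
spanning tree with Prim's algorithm (O(n²) dense implementation; the
"adjacency" structure is simply the full distance matrix). MSTs are unique
in total weight but not in edge set under ties, so ties are broken toward
the smallest vertex index, making the edge set — and everything downstream —
deterministic. Clusters are the components left after deleting inconsistent
edges, in one of two modes: every edge longer than a threshold (default
10 px, the operating point for 40× patches), or the k longest edges (used
to reproduce a fixed cluster count). Deleting k edges from a tree leaves
exactly k + 1 components.

Summary conventions: a singleton cluster has all distance statistics equal
to 0 (rather than undefined) so aggregate features stay well-defined;
cluster "area" is the convex hull of member centroids (0 for < 3 or
collinear members), with the sum of member nucleus pixel areas available as
an alternative; the inter-cluster MST connects cluster centroids (means of
member coordinates), not nearest member pairs — the centroid reading
matches how the inter-cluster structure is visualized, and member-pair
linkage is noted as a possible variant.

## The 26-feature descriptor

Features follow a per-cluster-then-aggregate grammar: for each cluster the
nucleus-to-nucleus pairwise distances (min/max/total/mean), the
intra-cluster MST edge weights (min/max/total), and the hull area are
computed; "total X" sums the per-cluster values and "average X" divides the
sum by the cluster count, which fixes the reading of every ambiguous name
(e.g. *total intra-cluster nucleus-to-nucleus maximum distance* = Σ over
clusters of that cluster's max pairwise distance). Eight features describe
the cross-cluster arrangement (centroid-to-centroid min/max/total/mean and
inter-MST min/max/total/mean); with a single cluster all eight are 0 so the
vector is always complete for downstream models. The order of
`feature_names()` is frozen; units are px, px², and a count. Rigid motions
leave all 26 features unchanged; scaling coordinates by s scales distances
by s and areas by s².

## Feature selection

Each of seven methods casts one boolean vote per feature; ≥ 4 votes selects
(the printed reference matrix in `data/reference_votes.csv` yields 16 of
26). How each method binarizes is a design choice: score-producing methods
(the four filters plus RFE and permutation importance) mark their top 16,
matching the selected-set size, while the Boruta-style procedure uses its
native confirm/reject decision. Chi-square requires non-negative inputs, so
features are min-max scaled to [0, 1] first. The wrapper base estimator is
a random forest (500 trees, seeded). The Boruta step is this package's own
implementation of shadow-feature all-relevant selection (30 rounds of
column-permuted shadows, a hit when a real feature's importance beats the
best shadow, one-sided binomial test at α = 0.05); it exists because no
Boruta package is part of this stack. Constant features are excluded from
every method's selection regardless of estimator noise. Information gain is
mutual information estimated on the continuous features; Fisher score is
the between-class to within-class variance ratio.

## Classification

Features are z-scored, (x − μ)/σ with the population σ, fitted on training
data only; zero-variance columns map to 0. The "variance" symbol in the
scaling formula denotes the standard deviation, i.e. this is the ordinary
z-score.

The stacking ensemble is implemented directly (not via a library stacker)
so the meta-feature contract is explicit: the four base learners (k-NN
k = 5; random forest, 300 trees; gradient boosting; XGBoost, 200 rounds)
produce out-of-fold class-probability vectors under 5 stratified inner
folds, giving a meta matrix of width 4 × n_classes on which a
logistic-regression meta learner is trained; probabilities rather than hard
labels keep the meta step smooth. Everything is deterministic under the
seed. Base-learner hyperparameters are sensible fixed defaults; there is no
hyperparameter search.

The default evaluation protocol trains once on a stratified 80 % split and
scores five disjoint stratified splits of the held-out 20 %, reporting one
metrics row per split plus their arithmetic mean — an unusual protocol, but
the one this pipeline standardizes on; conventional stratified 5-fold CV is
available via `mode="cv"`. Multiclass precision/recall/F1 are macro-averaged
one-vs-rest; binary metrics come from TP/TN/FP/FN with the second class as
positive; zero-denominator quantities are reported as 0 and flagged.

k-medoids is a from-scratch PAM (greedy BUILD, then best-improvement SWAP
to convergence) with Euclidean dissimilarity on the standardized table —
written here because no k-medoids implementation is part of this stack.
BUILD+SWAP has no random step, so results are reproducible by construction.
k defaults to the number of grade groups (3 multiclass, 2 binary). Scoring
against known grades uses the accuracy-maximizing one-to-one cluster-to-
label mapping, found exhaustively (k ≤ 5); note this optimal mapping biases
null-model accuracy slightly above chance.

## Synthetic data

`generate_patch` emulates what the pipeline measures, not tissue realism:
elliptical nuclei (radii 5–9 px) placed uniformly within discs of radius
`cluster_spread` around cluster centers that keep a minimum separation,
rendered through the same Beer–Lambert model the deconvolution inverts
(nuclei at hematoxylin concentration 1.0 with a trace of eosin, background
at eosin 0.25), plus Gaussian pixel noise (σ = 4). Disjointness is enforced
by rejection sampling with an error after a bounded number of tries —
random sequential packing saturates near 55 % of hexagonal density, which
caps feasible member counts per disc and sized the presets. Grade presets
(grade3: 4 loose clusters; grade4: 7 mid-density; grade5: 10 dense) are
qualitative emulations of architectural trends only. Because cluster radii
are hard-bounded, centers ≥ 5× spread apart guarantee inter-cluster gaps
above the 3× spread cut threshold, which is the geometry the recovery tests
rely on.

What passing on synthetic patches does **not** show: robustness to
overlapping/touching nuclei beyond the generator's geometry, stain
variability across scanners, out-of-focus regions, or stroma that mimics
chromatin saturation. Real-slide performance claims are outside this
package's scope.

`generate_feature_table` draws per-class Gaussians over the 26 features.
"Effect size d" means univariate Cohen's d per feature: adjacent grade
means differ by d·σ in every feature, monotone in grade (a grade that
affects cluster architecture moves many features together); d = 0 gives
identically distributed classes, so classifiers must fall to chance.
Baseline magnitudes (distances of tens to hundreds of px, areas of
thousands of px², ~8 clusters; σ = 15 % of baseline) approximate a 512 px
patch. Rows are clipped at 0 since every feature is non-negative.

## Problem sizes

The test and acceptance runs use 512 px patches (20 for detection rates),
200 random point sets of ≤ 7 vertices for exhaustive MST verification, 50
random cluster geometries for the feature oracle, 10⁴ pixels for the stain
round trip, and n = 300 (100 per grade) feature tables for classifier
recovery — sizes at which the exhaustive oracles stay exact and the whole
verification completes in well under a minute.

## Known limitations

- The modified normalization is kept bit-faithful to its printed form even
  though it breaks the classical self-normalization identity; users wanting
  classical Reinhard behaviour should normalize elsewhere.
- The 10 px cut threshold is magnification-specific; at other resolutions it
  must be rescaled by the user.
- Segmentation is classical (threshold + watershed); heavily overlapping
  nuclei beyond what distance-transform markers can separate are fused.
- Exact re-derivation of the reference vote matrix from data is impossible
  without the original private dataset; the fixture freezes the published
  votes and the tests verify the voting arithmetic and the scoring methods'
  behaviour on planted structure instead.
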