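# Methods

## The dispersion (ITH) score

A lesion's in-mask voxels are partitioned into n_c subregion clusters by
unsupervised clustering of local radiomic descriptors. For cluster
l = 1..n_c let m_l be its number of connected components, V_l,max the size
of its largest component and V_total the lesion size; the score is

    score = 1 − (1/V_total) · Σ_l V_l,max / m_l .

Each cluster contributes its largest component *diluted* by its component
count, so the score is 0 exactly when every cluster is one connected
block and approaches 1 as clusters shatter into many dispersed fragments.
Splitting any component of any cluster into two nonempty parts can only
increase m_l and (weakly) decrease V_l,max, so the score never decreases
under fragmentation — the property that makes it a dispersion measure.

Connectivity is 26-neighbourhood in 3D (faces, edges, corners; Chebyshev
distance 1). In 2D the planar analogue, 8-connectivity, is the default
(4-connectivity is available via `connectivity="4_2d"`). Component sizes
are voxel counts, not mm³: the score is a ratio of counts and therefore
invariant under uniform voxel spacing; this also makes it exactly
invariant under axis flips, 90° rotations and any relabeling of clusters
(the per-cluster terms are summed with `math.fsum`, so the result is the
correctly rounded sum and does not depend on summation order).

The 2D path scores the largest axial slice (ties broken toward the lowest
slice index); the 3D path scores the whole volume. Both are produced by
`compute_ith`, which also returns the full per-cluster component audit.

## Local radiomic descriptors

Every in-mask voxel is described by the 2×2 (2D) or 2×2×2 (3D) window
anchored with the voxel at its minimum corner; even windows have no
centre, and corner anchoring gives a deterministic, mask-complete
assignment. Windows that would protrude past the crop are served by
edge-replication padding. Out-of-mask voxels inside a window participate
as acquired, as in patch-based extraction on real images where the
surrounding parenchyma is real tissue; an optional `masked_fill` flag
replaces them with the nearest in-mask intensity instead (note that this
duplicates values and perturbs the window's intensity multiset, which is
why it is off by default).

Intensities are discretised per window with a fixed bin width (default
25 HU) *relative to the window minimum*, so adding a constant to all
intensities leaves every discretised feature unchanged.

A 2-voxel-wide window has a special property: all of its voxels are
mutually adjacent under the 8-/26-neighbourhood, which collapses each
texture matrix to a closed form over the window's voxel pairs —
co-occurrences are all ordered pairs, gray-level zones are the per-level
voxel sets, dependence counts are same-level multiplicities, run lengths
are 1 or 2. The implementation exploits this to compute all features
fully vectorised across windows; a deliberately slow per-window reference
implementation in the test suite checks every feature value.

The default registry has 60 features: 16 first-order, 12 GLCM, 11 GLRLM,
7 GLSZM, 9 GLDM, 5 NGTDM. The registry is configuration-driven (classes
can be switched off) and the count is reported, not hard-coded. Shape
descriptors are computed once per lesion and kept out of the clustering
matrix — the shape of a fixed 2-wide window carries no information.
Degenerate values on constant windows follow the usual conventions:
contrast-, entropy- and correlation-like features are 0; NGTDM coarseness
is capped at 10^6.

Features are z-scored per lesion (population SD); constant features are
dropped from the clustering input and recorded. Per-lesion normalisation
is required for single-lesion scoring; no cross-cohort mode is offered.

## Subregion clustering

k-means with the cluster count fixed a priori at n_c = 6, k-means++
initialisation, 10 restarts, tolerance 1e-4, at most 300 iterations and a
fixed seed. k is reduced to the number of distinct feature rows for tiny
or degenerate lesions, and empty clusters are compacted, so the obtained
count `nc_effective` may be below 6; it is never tuned per dataset. A
perfectly homogeneous lesion (all descriptors constant) short-circuits to
a single cluster and scores 0. Note the converse property: because n_c is
fixed rather than data-driven, a homogeneous-but-noisy lesion is still
split six ways and scores *high* — the score measures the dispersion of
the forced partition, not whether partitioning was warranted.

## Synthetic phantoms

Phantoms exist so that every pipeline stage can be tested against an
analytically known ground truth without any data download. The default
geometry is *laminar*: the ball-shaped mask is cut into stacked axial
slabs (one slab per planted fragment, masses proportional to the
requested volume fractions), and each subregion carries a deterministic
texture pattern — a fixed multiset of intensity levels assigned over the
eight parity sublattices of the voxel grid, so every window inside a slab
sees exactly the same discretised multiset. Subregion means step by 40 HU
and the pattern level step is 28 HU, deliberately off the 25 HU bin width
so that additive noise (default SD 0.5 HU) cannot flip a level across a
bin edge. A one-voxel layer at every slab interface is excluded from the
mask while the image continues the lower slab's pattern there; combined
with corner-anchored windows this guarantees that no in-mask window
straddles two subregions. Fragmented subregions are realised as multiple
slabs, which the interface gaps keep 26-disconnected.

This construction is what "separable" means here: subregions are
separable *by construction*, so pipeline recovery is limited only by the
clustering stage, and on the separable preset the recovered partition
matches the planted one (ARI 1.0) and the pipeline score equals the
analytic score of the planted map. A second geometry, `blobs`, grows
subregions from well-separated seeds by 6-connected region growing with
sinusoidal texture; its irregular interfaces produce partial-volume
windows whose descriptors lie between and beyond the pure-class values,
which is realistic but makes exact recovery impossible — a useful
robustness setting, not a recovery benchmark.

What the phantoms do *not* emulate: lung anatomy, partial-volume mixing
at subregion interfaces (excluded by design in the laminar geometry),
scanner noise spectra and reconstruction kernels, and continuous texture
variation. Passing the recovery tests therefore shows the pipeline is a
faithful implementation of the construction, not that six clusters
recover biologically true habitats on real CT.

## Synthetic cohorts

Cohort tables emulate the schema and marginal structure of a multicenter
lung-nodule cohort: three centers (proportions 600/310/391 of 1301, the
third center tagged as the fixed external split), sex, age, nodule size
(lognormal, median 17.9 mm), CT density (pGGN/SSN/SN at 50/25/25%), lobe
location, eight binary CT signs at their cohort rates, and 2D/3D ITH
scores drawn from Beta distributions matching the published medians (0.5
and 0.8). The binary VPI outcome follows a logistic model over planted
effects — defaults: 3D ITH score 1.2 log-odds per SD (strongest), nodule
size 0.7, density 0.5 per level, pleural indentation 0.4, 2D score 0.3,
spiculation 0.3 — with the intercept calibrated by bisection so the
expected prevalence equals the requested 13.4%. Features are mutually
independent given the planted effects; real clinicoradiologic variables
are correlated, so absolute model performance on these tables is not a
forecast of clinical performance.

## Class balancing

SMOTE oversamples the minority class to parity by convex interpolation
between a minority row and one of its k = 5 nearest minority neighbours
(continuous features interpolated, categorical copied from the anchor);
Tomek links — mutual nearest-neighbour pairs with opposite labels — then
lose their majority member, iterated to a fixpoint so the cleaned set is
link-free. Distances use z-scored continuous features plus one-hot
categories weighted 1/√2 (a category mismatch adds unit squared
distance). Balancing is applied to training rows only, and inside each
cross-validation fold's training split, never to validation or external
rows.

## Stacking ensemble

Six base learners — AdaBoost, gradient-boosted trees, histogram gradient
boosting, LightGBM, random forest, XGBoost — are each tuned by
grid-searched stratified 5-fold cross-validation maximising AUC (ties go
to the earliest grid point). Hyperparameter grids are small and
documented in `default_grids()` (3–4 points per learner); `fast_grids()`
is a single-point preset for quick experiments and simulation studies.
Categorical inputs are one-hot encoded for every learner except histogram
gradient boosting, which consumes native category codes. Out-of-fold
probabilities from the same folds form the 6-column meta-feature matrix
(columns in fixed alphabetical learner order) on which a logistic
regression meta-classifier is fitted, its C tuned over {0.01, 0.1, 1, 10}
by 5-fold CV AUC. External prediction runs the refitted base models and
the meta-classifier; the default operating point is 0.5 and is
configurable per site.

Comparators: the clinicoradiologic model is the identical stack without
the two ITH scores; the radiomics signature runs a three-stage selection
on a per-patient whole-lesion feature table — two-sample t-test filter
(default keeps P ≤ 0.5; the threshold is configurable, 0.05 being the
conventional alternative), Pearson pruning of |r| > 0.9 pairs keeping the
first column, then L1-penalised logistic regression tuned by 10-fold CV
deviance with the 1-SE rule — followed by a plain logistic signature on
the selected features.

## Attribution and ablation

For the linear meta-classifier, the Shapley value of meta-feature j on
the linear-predictor scale is exact and closed-form:
coef_j · (x_j − E[x_j]) with the expectation over a background set; the
test suite confirms equality with exhaustive 2^6 subset enumeration.
Input-feature attributions for the end-to-end stack use
permutation-sampling Shapley estimation (random feature orderings,
marginal contributions against background rows) with a Monte-Carlo
standard error reported; the default background is 100 training rows
drawn with a fixed seed. Percent contributions normalise mean absolute
attributions to 100.

The ablation retrains the stack on the top-k attribution-ranked features
for growing k, recording mean CV AUC and external AUC; the stopping step
is the last step before the external-AUC improvement first falls below
the plateau tolerance (default 0.005 AUC, configurable — no canonical
value exists). The full trace is always returned.

## Evaluation

AUC is the pairwise concordance probability with ties at 1/2. PR-AUC uses
the step-interpolation convention (average precision), under which random
scores give PR-AUC ≈ prevalence. Threshold metrics report precision 0
with an explicit flag when nothing is predicted positive. Decision-curve
net benefit is TP/n − (FP/n)·p_t/(1−p_t) on a default grid 0.01–0.50 in
steps of 0.01 (the range where the positive-class prevalence stays below
one half), with treat-all and treat-none references; net benefit never
exceeds prevalence and attains it only for a perfect classifier.
Leave-one-center-out validation holds each center out exactly once; a
held-out center with a single outcome class is flagged and its AUC
reported as NaN rather than fabricated.

## Numerical and design notes

- Coordinate convention: 0-based voxel indices, axis order (z, y, x),
  z axial. NIfTI axes are transposed on load/save. Affine agreement is
  checked to 1e-3 to tolerate header rounding.
- No resampling is performed by default; scores use voxel counts and are
  spacing-invariant by construction.
- Scores are invariant under `crop_to_mask` for any margin ≥ 1 (the
  window reach); a margin-0 crop discards the one-voxel context ring that
  windows can see, and the edge-replication fallback then applies. With
  `masked_fill=True` the invariance holds for every margin.
- Determinism: every stochastic stage (phantom and cohort generation,
  k-means, balancing, learners, attribution sampling) takes an explicit
  seed; fixed seeds reproduce label maps, tables, models and predictions
  bit-for-bit, and fitting never sees external rows.
- Problem sizes in the test suite and acceptance script are desk-scale by
  design: 32³ phantoms (≈7,700 mask voxels) over 20 seeds, cohorts of
  n = 600–1,301, 50 permutation replicates with the single-point grid
  preset, and oracle checks on thousands of random label maps up to
  20×20 and 12×12×12.

## Known limitations

- The per-window texture estimates rest on 4–8 voxels and are inherently
  noisy; cluster recovery on real CT depends on how strongly true
  habitats differ relative to that noise.
- The fixed n_c = 6 partitions even homogeneous tissue; interpret the
  score as dispersion of the forced partition.
- Synthetic cohorts have independent features and a correctly specified
  logistic outcome; they validate pipeline mechanics (no leakage,
  calibration of the null, signal detection), not clinical effect sizes.
- Probability calibration of the ensemble after resampling is not
  analysed here.
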