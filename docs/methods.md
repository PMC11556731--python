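# Methods

This note records the models, conventions and design choices behind texfuse,
and what the synthetic experiments do and do not demonstrate.

## Problem setting

The pipeline targets multiclass classification of 8-bit grayscale images
whose classes differ in texture rather than in geometry — the motivating
application is four-way chest-radiograph triage (COVID-19, bacterial
pneumonia, viral pneumonia, normal) from heterogeneous public collections
with strong class imbalance.  Two complementary representations are fused:
second-order texture statistics (GLCM/Haralick features), which summarize
local gray-level co-occurrence structure, and deep convolutional features,
which capture higher-level spatial patterns.  A class-conditional-mean
filter then removes features that carry no first-moment class signal before
a gradient-boosted classifier is fit.

## Preprocessing

Order: resize → median denoise → histogram equalization.  All stages emit
uint8 and round half-up, so the pipeline is bit-stable.

- **Area resize.**  Separable pixel-area-overlap weights; downscaling by an
  integer factor k is exactly the mean of each k×k block.  This is the
  "inter-area" scheme appropriate for downscaling (no aliasing from point
  sampling).  Default output 224×224 to match the deep extractor's standard
  input; synthetic experiments keep the native 64×64.
- **Median filter.**  Rank filter, reflect border, default 3×3, kernel must
  be odd.  A rank filter guarantees output values are members of the input
  neighborhood, so the intensity range is preserved structurally.
- **Equalization.**  Classic integer CDF-min lookup:
  `lut[v] = round(255·(cdf[v] − cdf_min)/(N − cdf_min))`.  Monotone, hence
  rank-preserving; a constant image maps to itself (degenerate N = cdf_min
  case); re-application moves no pixel by more than one level.
- Color inputs are reduced to luminance (BT.601) at ingestion.

## Augmentation and balancing

Twelve transforms with fixed parameter ranges and firing probabilities:
rotation (−50..20°, p 0.2), horizontal/vertical flip (p 1.0), shear
(−40..40°, p 0.2), gamma contrast (0.5..2, p 0.2), sigmoid contrast (gain
5..10, p 0.2), linear contrast (Δ −0.2..0.2 of full scale, p 0.2), elastic
(α 60, σ 4, p 0.2), polar/radial distortion (magnitude −0.2..0.7, p 0.2),
jigsaw (grid 4..8, p 0.2), invert (p 1.0), polarize (factor 0.5..2, p 0.2).

Composition rule: one augmented image = the original passed through a
freshly sampled pipeline in which each transform fires independently with
its probability, in listed order; drawn parameters are logged.  The p = 1.0
entries participate in the same mechanism rather than being applied
unconditionally — unconditional inversion of every augmented image would
systematically flip the intensity statistics of the oversampled classes.

Conventions for grayscale: "polarize" (a saturation operation in color
imagery) is implemented as contrast scaling about the image mean; the jigsaw
permutes equal-sized blocks of the largest g×g-divisible region (margins of
at most g−1 pixels stay in place), so it is exactly histogram-preserving.
Geometric transforms resample bilinearly with reflected borders.

Balancing oversamples every minority class to the majority count with
augmented copies of uniformly chosen (with replacement) originals.
Originals are never mutated.  Sub-streams are keyed by (class index, copy
index) from one seed, so results do not depend on processing order.

## GLCM features

Intensities are quantized to L uniform bins over [0, 255] (default L = 32 —
small enough that 64×64 images populate the matrix, large enough to retain
contrast structure).  Pair counts use the conventional chessboard offsets
(0° → (0, d); 45° → (−d, d); 90° → (−d, 0); 135° → (−d, −d)); matrices are
symmetrized and normalized.  Note that some library implementations round
d·(sin θ, cos θ) for diagonal angles, which differs from the chessboard
convention at d ≥ 2; the in-package counter is exact at all distances and is
verified against brute-force pair enumeration.

The static descriptor is a frozen, ordered list of 25 statistics per matrix,
averaged over the four angles at each configured distance (default d = 1):
contrast, dissimilarity, homogeneity (inverse difference moment), energy
(angular second moment), entropy, correlation, sum-of-squares variance, sum
average, sum variance, sum entropy, difference variance, difference entropy,
the two information measures of correlation, autocorrelation, cluster shade,
cluster prominence, maximum probability, inverse difference, inverse
difference normalized, inverse difference moment normalized, maximal
correlation coefficient, the two marginal means, and the row-marginal
entropy.  Entropies are base-2 with 0·log 0 := 0.  Degenerate guards:
correlation of a point-mass matrix is 1 (zero marginal variance); the
maximal correlation coefficient returns 0 when fewer than two gray levels
have positive marginal mass.  Angle averaging over the full set makes the
descriptor invariant to 90° image rotations (tested to 1e−9).

## Deep features

The extractor contract is minimal — `output_dim` plus a deterministic
batched image→vector map — so stubs, random projections and convolutional
stacks are interchangeable throughout the pipeline and in tests.

The default topology (`vgg16_truncated_dense1024`) is a VGG-16-style stack:
five conv blocks (64-64 / 128-128 / 256×3 / 512×3 / 512×3, all 3×3, ReLU,
2×2 max-pool) then flatten → dense(1024) → ReLU → dense(1024).  The second
dense layer's **linear** output is the 1024-dimensional feature tap (taking
the pre-activation keeps the full vector informative; a ReLU tap would
zero roughly half the coordinates under random weights).  It runs
feed-forward in NumPy (im2col + BLAS); grayscale input is replicated to
three channels and scaled to [0, 1].  Weights are seeded He-normal draws or
an `.npz` produced by `save_weights`; nothing is downloaded.  A
`width_scale` knob thins the channel counts for fast experiments.  The
`random_projection` topology (seeded Gaussian projection of the flattened
image, tanh-squashed) is the practical choice for large synthetic runs and
is the pipeline default; `mean_intensity` is a one-dimensional stub used in
contract tests.

## Mean-dropout feature selection

The filter drops every feature whose class-conditional means collide for at
least one class pair; per-class keep-sets are intersected.  The printed
strict form (exact mean equality) is recovered at tolerance ε = 0 and is
what the brute-force equivalence tests check.  For continuous features exact
equality of empirical means is a measure-zero event, so the strict filter
never drops anything; the generalization treats means as equal when
|Δ| ≤ ε·max(1, pooled within-class sd of the feature), with ε = 0.05 by
default.  The max(1, ·) floor keeps the threshold meaningful for features
with sub-unit scale.  Selection is invariant to row and column order,
antitone in ε (larger tolerance ⇒ smaller keep-set), and equivariant under
joint rescaling of a feature and an absolute tolerance.  Single-class tables
select everything (the defining condition quantifies over an empty set) with
a warning; missing values are rejected rather than imputed.

## Classification and evaluation

- **Split.**  Stratified train/test with largest-remainder apportionment of
  the test fraction (default 0.2): total test size round(N·f), per-class
  floor(N_y·f) plus remainder seats by largest fractional part, ties by
  class name.  Four balanced classes of 2521 at f = 0.2 therefore give a
  2017-row test set (504+504+504+505).
- **Model.**  XGBoost, softmax probabilities for K > 2 (logistic for K = 2),
  single-threaded for determinism.  Grid search is exhaustive over the
  declared grid — by default the full published grid (booster
  {gbtree, gblinear}; colsample_bytree, subsample {0.4, 0.6, 0.8, 1};
  learning rate {0.01, 0.1, 0.2, 0.4}; max depth {2, 3, 4, 6}; estimators
  {200..500}) — scored by 3-fold inner stratified CV accuracy, ties broken
  by grid order, winner refit on the full training partition.  The pipeline
  default is the single tuned combination (gbtree, colsample 1, lr 0.1,
  depth 6, 200 estimators, subsample 0.8), keeping end-to-end runs at desk
  scale; any sub-grid can be configured.
- **Report.**  Confusion matrix; per-class P/R/F1/support with the 0/0
  convention "report 0 and warn"; macro (unweighted) and weighted
  (support-weighted) averages; one-vs-rest AUC per class (pairwise
  concordance with ties at half, via scikit-learn, verified in tests against
  explicit pair enumeration).
- **Cross-validation.**  Stratified k-fold; within each fold the selection
  is refit on the training partition only and applied to the held-out fold —
  selecting on the full table before splitting leaks held-out information
  into the feature set, and a dedicated test demonstrates that failure mode.
  The fold count is a required parameter with no privileged default.  The
  fold-accuracy sd is the population sd of the k values.
- **Export.**  The bundle (joblib) carries the fitted model, the selected
  feature names with tolerance and class means, and the preprocessing/GLCM
  configuration; reload reproduces predictions exactly and the bundle size
  in bytes is reported.

## Synthetic data

Texture families: Gaussian-smoothed white noise (smoothing scale = blur σ,
normalized to unit field sd before amplitude scaling), checkerboard (period
= scale), and random blob fields (disk radius = scale, ~35% coverage).  All
oscillate around gray level 128 with a configurable amplitude and additive
Gaussian pixel noise, clipped (not wrapped) to [0, 255].  The smoothing
scale controls the spatial correlation length and therefore the short-range
GLCM contrast, which is what makes the classes separable by the static
features.  Default study conditions for the end-to-end check: four classes
(scales 1 / 2.5 / 6 plus a period-4 checkerboard), 100 images per class,
64×64, amplitude 120, noise sd 8 — chosen once as a clearly-but-not-
trivially separable texture regime at desk scale.  Feature-table fixtures
draw i.i.d. Gaussians with declared per-class means, so the ground-truth
informative set is known exactly.

What the synthetic data does **not** emulate: anatomy (ribs, lungs,
devices), acquisition heterogeneity across hospitals, label noise, and
inter-class texture overlap of real radiographs.  Passing tests therefore
demonstrate the correctness and reproducibility of the machinery — not
clinical performance; the published headline accuracies depend on the
external radiograph collections and are out of scope here.

## Numerical conventions

Half-up rounding after every float image stage; seeds fan out to
order-independent per-item sub-streams via `SeedSequence(seed, spawn_key)`;
per-stage seeds derive from one global seed by hashing the stage name;
reports serialize with sorted keys so byte-identical JSON is the
reproducibility criterion.  Problem sizes in tests (≤ 4×100 images at 64×64,
small hyperparameter grids) are the package's chosen desk-scale defaults;
all counts with structural meaning (25 features, 1024 dims, 2521 per class,
2017 test rows) are computed, never hard-coded, in the checks.

## Known limitations

- The maximal correlation coefficient uses a dense eigendecomposition; for
  L = 256 quantization levels this is the slowest of the 25 features.
- `gblinear` ignores tree-specific grid axes (depth, subsample); the grid
  enumerates the combinations regardless, as printed.
- The deep extractor is feed-forward only; fine-tuning of the published
  training schedule (lr 0.001, momentum 0.9, weight decay 1e−5, batch 32,
  50 epochs, ReLU, dropout 0.3, early-stop patience 10) is recorded as
  configuration but not executed.
- Histogram equalization is global; adaptive (CLAHE-style) variants are out
  of scope.
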