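# Methods

## Problem setting

Drug-target interaction (DTI) prediction is cast as binary classification
of (drug, protein) pairs. Each entity carries a dense real-valued feature
vector (in practice, a low-dimensional embedding of the drug's and
target's positions in multiple biological networks); a pair's feature
vector is the concatenation of its drug and target vectors. Known
interactions are positives; pairs with no recorded interaction are treated
as negatives for training and evaluation.

## The cascade forest

The classifier is a cascade (deep) forest. Layer `l` holds a group of
estimators — by default three GOSS-boosted tree classifiers and three
extremely randomized tree ensembles (`3LGB-3ET`; `2LGB-2RF-2ET` and
`3LGB-3RF` are available as presets). Each estimator emits a 2-dimensional
class-probability vector per instance. During training these vectors are
produced by stratified k-fold cross-validation (k = 5 by default), and
each training instance receives its vector from the one fold model that
excluded it — an out-of-fold (OOF) prediction. An alternative reading of
layer-wise class-vector generation would average the k-1 models trained
*on* the instance; that choice leaks the instance's own label into the
stacked feature and is deliberately not used. The layer's class vectors
are appended to the *original* features (width `D + 2·E` for `E`
estimators), and the next layer trains on the augmented matrix.

Before any layer is grown, a stratified validation split (20% of the
training pairs) is held out. After each layer, the cascade-so-far is
scored on that split by accuracy at threshold 0.5; growth stops when the
score fails to improve on the best layer by at least `tolerance = 1e-4`
for `patience = 1` consecutive layers, or at `max_layers = 10`. The
retained model is truncated at the best-scoring depth. At inference each
estimator's output is the mean of its k retained fold models'
probabilities (no refit on the full training set), and the cascade's
prediction is the mean class vector of the final layer; the predicted
label is 1 iff `p1 >= 0.5`.

Estimator seeds are derived deterministically from the master seed via a
seed sequence keyed by (layer, estimator, fold), so runs are reproducible
while estimators stay decorrelated.

## The boosted-tree core

The `goss_gbdt` estimator is implemented from first principles rather than
wrapping a library, because its split-finding machinery is the point of
the package:

* **Binning.** Each feature is discretised into at most `k = 255`
  quantile bins; a value lands in bin `#(edges <= value)`, so the mapping
  is monotone and constant columns collapse to one bin. Edges are stored
  for scoring new data.
* **Histograms.** Per node and feature, the weighted gradient sum and raw
  instance count are accumulated per bin in one pass. A sibling's
  histogram is obtained by subtracting the smaller child's from the
  parent's, never by a second data pass; counts are exact and gradient
  sums agree with a direct build to ~1e-9.
* **Gain.** Splitting feature `j` at bin boundary `d` is scored by the
  gradient variance

      V_j(d) = (1/n) [ (Σ_left g_i)² / n_l + (Σ_right g_i)² / n_r ].

  Under GOSS the gradient sums of the sampled small-gradient set are
  amplified by `(1-a)/b` while `n_l, n_r` remain raw member counts; with
  the full node and no sampled set this reduces exactly to the plain
  variance. No second-order (hessian) statistics are used: the gain is
  first-order by design, and leaf values follow the same convention. The
  normalisation `1/n` is the current node's size throughout.
* **Growth.** Trees grow leaf-wise (best-first): the frontier leaf with
  the largest gain improvement is always split next, subject to
  `num_leaves <= 200`, node depth `< max_depth = 11` (the root has depth
  0, so `max_depth = 1` yields a stump), `min_child_samples = 5` per
  side, and strictly positive improvement over the unsplit node's
  `(Σg)²/n` term. Ties in the gain search break toward the lower feature
  id, then the lower threshold.
* **Boosting.** Binary logistic loss; the initial score is the log-odds
  of the base rate; per round the negative gradient is `g_i = y_i - p_i`,
  a fresh GOSS partition (`a = 0.2`, `b = 0.1`; top set by absolute
  gradient, ties toward lower index; both sizes by ceiling) selects the
  round's training instances, one tree is grown, and its learning-rate
  scaled (0.1) weighted-mean-gradient leaf values are added to the raw
  scores. GOSS sorts on |g|: the magnitude is the meaningful ordering for
  signed gradients.
* **EFB.** Exclusive feature bundling greedily merges sparse, mutually
  (near-)exclusive features into single encoded columns: features are
  visited by descending nonzero count and accepted into the first bundle
  whose accumulated conflicts stay within `max_conflict_rate · n`
  (default 0 — strict exclusivity). Member values shift into disjoint
  positive intervals by cumulative-maximum offsets; a conflict-free
  bundle decodes exactly whenever the offset additions are exact in
  floating point (always for integer-valued features). Features with
  negative values stay as untransformed singletons, since the interval
  encoding requires non-negative values. EFB is off by default: the
  synthetic features are dense, making it a no-op there.

Defaults `n_estimators = 400`, `max_depth = 11`, `num_leaves = 200` (and
500 trees for extra-trees, 400 for random forest) follow the
grid-searched operating point; the grid itself (4 x 5 x 5 candidate
settings for the boosted trees) is exposed in `pipeline.TABLE1_RANGES`
and can be re-run with `grid_search`, which scores each point by
stratified k-fold accuracy of the single estimator — not the full
cascade — to stay desk-scale.

## Metrics

Sensitivity, specificity, MCC, precision and recall are evaluated exactly
from the confusion matrix at threshold 0.5; zero denominators return 0
(and MCC returns 0 when any factor of its denominator vanishes) so every
metric stays bounded. ROC and PR curves sweep descending distinct score
thresholds — tied scores move together — with the ROC anchored at (0,0)
and (1,1) and the PR curve's left endpoint at recall 0 with the top
block's precision. Areas use the standard trapezoid
`½ Σ (x_{i+1}-x_i)(y_i+y_{i+1})`; a published variant of the AUC formula
with `(y_{i+1}-y_i)` in place of the sum does not compute an area and is
presumed a typo. The trapezoidal ROC area provably equals the
Mann-Whitney concordance statistic with ties counted one half, and the
test suite asserts the identity to 1e-12.

Note two distinct label-flip identities: relabeling the classes in both
truth and prediction swaps Sn with Sp (MCC unchanged); flipping the
*predictions* only negates MCC (and maps Sn to 1-Sn). No single operation
does both.

## Synthetic data generator

The generator emulates the role of network-embedding features. Latent
factors `U` (drugs) and `V` (targets) are standard normal with
`latent_dim = 8`; pair propensity is `U Vᵀ`; exactly the top
`density = 0.02` fraction of all pairs is labelled positive. Observed
features embed the factors into `feature_dim = 32` dimensions per side
through a random orthonormal (norm-preserving) map plus Gaussian noise
with `noise_sd = 0.5` — roughly unit per-feature signal-to-noise. The
default scale is 100 drugs x 150 targets (3 000 positives would be 20%;
at 2% there are 300), chosen to keep a full 5-fold cascade evaluation in
the minutes range on one CPU.

What the generator does *not* reproduce: the block/network structure of
real multi-network embeddings, heavy-tailed interaction degree
distributions, and — importantly — label noise in the negative universe
(real "unknown" pairs contain unobserved true positives; here unknowns
are true negatives by construction). Passing tests therefore demonstrate
correctness and learnability of the machinery, not field performance on
real pharmacological data.

A consequence of the bilinear label geometry deserves note: because the
class boundary is `u·v ≥ c`, it is linear in the drug⊗target
outer-product space but *not* axis-aligned in the concatenated features.
Tree ensembles must approximate it through interaction splits, and their
held-out AUC on the default dataset plateaus near the mid-0.80s —
including for full-strength library baselines — while a bilinear-aware
logistic model exceeds 0.94. The cascade's measured value on these
conditions is reported by `scripts/acceptance.py`, not assumed.

## Evaluation protocol

All positives plus an equal number of negatives drawn uniformly without
replacement from the unknown pairs are evaluated by k-fold
cross-validation over the positives (k = 5: 80%/20% train/test). Fresh
negatives are drawn per fold, with train and test negatives disjoint; a
documented option fixes one global negative draw instead. Every fold is
exactly class-balanced on both sides.

## Numerical and determinism choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`-derived generators; identical (data, config,
seed) reproduce models, predictions and written reports bitwise. Report
files carry repr-exact floats, sorted keys and no timestamps. A split is
accepted only when its variance exceeds the unsplit term by more than
1e-12, preventing noise-driven splits on constant-gradient nodes.
Degenerate inputs (single-class labels, empty nodes, unsplittable roots,
constant features) are either rejected with diagnostics or yield the
documented neutral results (single-leaf trees, all-zero histograms).

## Known limitations

* First-order gains only; no hessian weighting, categorical features,
  multithreaded kernels or GPU paths.
* EFB decoding is exact only within fitted value ranges and for values
  whose offset shift is exact in floating point.
* The early-stop validation split is held out once, not refolded per
  layer.
* Problem sizes in the shipped tests and the acceptance script are
  desk-scale (hundreds of pairs per fold, 50 boosting rounds per
  estimator) — the package's own choice of default experiment size.
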