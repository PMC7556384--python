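# Methods

## The model

`feruc` implements ensemble regression via response discretization. Given a
learning set (X, y) with X ∈ ℝ^{n×p} and a continuous response y, and a bin
count c:

1. **Discretize** y into c bins with one of four unsupervised schemes
   (random, even split, equal frequency, 1-D k-means).
2. **Train**, for each bin b, a regressor R_b on that bin's samples only,
   and — for the weighted aggregator — a one-vs-rest binary classifier C_b
   on the full training set, bin samples positive, everything else
   negative, optionally balanced first (random undersampling or SMOTE
   oversampling with k neighbours, default k = 5).
3. **Predict** a new sample x as

       ŷ(x) = Σ_b w_b(x) · R_b(x),   w_b(x) = p_b(x) / Σ_j p_j(x),

   where p_b(x) = C_b's positive-class probability. With the averaging
   aggregator no classifiers are built and ŷ is the plain mean of the
   R_b(x). Either way ŷ is a convex combination of the per-bin outputs.

The rationale: a single model trained on the full set is accurate near the
centre of the response distribution and poor at its tails, analogous to
class imbalance in classification. Restricting each regressor to a narrow
response band and routing new samples by feature-based band membership
trades a harder regression problem for an easier classification one.

The estimator is learner agnostic. The default base learner is a random
forest with 1000 trees; mtry follows the conventional forest defaults (p/3
for regression, √p for classification), and the classifier's probability is
the fraction of trees voting positive. Any object pair honouring
`fit`/`predict` and `fit`/`predict_proba` (probabilities in [0, 1]) can be
substituted through `BaseLearnerSpec`.

## Discretizers: conventions at the gaps

- **even split**: stable sort, contiguous blocks; the first `n mod c` bins
  get one extra sample. Bin sizes always differ by ≤ 1, duplicates
  included.
- **equal frequency**: starts from the even-split blocks, then every group
  of tied values moves to the lowest bin any of them tentatively occupies
  (a value on a cut point goes to the lower bin). Identical to even split
  on duplicate-free data; duplicates can unbalance bins or empty one
  (raised as an error naming the bin). This realizes the duplicate-induced
  imbalance that distinguishes the two schemes.
- **random**: a seeded permutation split into equal-as-possible blocks
  (not independent uniform assignment), keeping per-bin regressor
  training-set sizes comparable across methods — a bagging-like control.
- **k-means**: Lloyd's algorithm with k-means++ initialization, best of
  `restarts` (default 10) runs by WCSS, 300 iterations max; clusters
  relabelled 1..c by ascending centre. An exact 1-D dynamic-programming
  solver exists in the test suite as an oracle only.

Ensemble fitting requires every bin to hold ≥ 2 samples (a regressor
cannot be trained on fewer); violations raise an error naming the bin and
method rather than silently degrading.

## Resampling conventions

Oversampling grows the minority exactly to the majority count; synthetic
rows are convex interpolations x + u(x′−x), u ~ U[0,1], between a minority
row and one of its k nearest minority neighbours (Euclidean distance on
raw features — pre-standardize if feature scales are heterogeneous). If
the minority has m ≤ k members, k is clamped to m−1; a singleton minority
is balanced by duplication. Undersampling never synthesizes: it keeps all
minority rows and a seeded without-replacement subset of the majority.
Inside `ensemble.fit`, per-bin resampling seeds derive from the master
seed; `ResamplingSpec.seed` applies only when the resamplers are called
directly.

## Weighting edge cases

Probabilities outside [0, 1] are contract violations and raise. An
all-zero probability vector (the normalization would divide by zero) falls
back to uniform weights, preserving convexity and degrading gracefully to
averaging. A c=1 model has a single weight of 1 and is bit-identical to
the base-case regressor trained with the same derived seed — the
degenerate anchor the test suite exploits.

## Seed management

A master seed feeds `numpy.random.SeedSequence((master, bin, component))`
sub-streams for each bin's regressor, classifier and resampler, plus the
discretizer; derived seeds stay below 2^31. Adding a bin therefore never
perturbs the randomness of existing bins, and the base case uses the same
derivation as bin 1's regressor, which is what makes the c=1 degeneracy
exact. Per-target seeds in the evaluation grid derive from a hash of the
target *name*, so grid reports are invariant to target column order.

## Evaluation

Regression skill is R² = 1 − SSres/SStot about the observed mean
(unbounded below; negative means worse than the horizontal line; a
constant observed vector raises). Classifier reporting uses accuracy,
precision, recall and F1 with documented conventions: precision := 0 when
no positives are predicted, F1 := 0 when precision + recall = 0. Hard
labels use the standard 0.5 probability threshold.

Scoring the bin classifiers on a test set needs a "true bin" per test
sample, which training never defines. Convention: for order-respecting
discretizers the true bin is the bin whose training response interval
contains the sample, with boundaries at midpoints between adjacent bins'
training extremes (a boundary value goes lower); for the random
discretizer, test samples are randomly assigned under a derived seed,
mirroring the training-time rule.

Percentage difference vs the base case is the mean over targets of
100·(method − base)/|base|; targets with base exactly 0 are excluded with
a warning. With near-zero or negative bases the magnitude is unstable —
the grid reports flag this. Paired t-tests across targets are reported
without multiple-testing correction (noted in the report header);
identical score vectors return t = 0, a nonzero constant difference
raises a degenerate-test error rather than reporting an infinite
statistic.

Grid cells whose fit fails (e.g. k-means produced a one-sample bin) are
recorded in the report's error list and the grid continues.

## The synthetic generator

The generator emulates — at one-tenth scale, 700 training and 300 test
samples, 50 features, 2 targets — a perturbation-response prediction task
whose response distribution has regime structure:

- each sample draws a latent regime (default 3, uniform);
- regimes shift the mean of 5 informative features by a unit-norm
  direction scaled by `feature_shift` (default 1.0 — bin membership is
  predictable from features, but imperfectly);
- the response is `regime_separation` (default 8.0) times the regime index
  plus a regime-specific unit-variance linear map of the centred features
  plus Gaussian noise (`noise_sd`, default 0.5), so response bands are
  largely disjoint;
- a fraction `outlier_fraction` (default 0.05) of samples receive
  heavy-tail response contamination with scale
  `outlier_scale × regime_separation`.

The contamination default is deliberate: heavy-tailed responses are
typical of perturbation expression data and are the condition under which
response-partitioned ensembles help — outliers corrupt a global model's
predictions everywhere, but under order-respecting discretization they are
confined to the edge bins, whose weights are small for central samples.
With `outlier_fraction=0` and moderate feature signal, a well-tuned global
forest routes regimes about as well as the explicit bin classifiers and
the ensemble's advantage disappears; passing trend tests therefore speak
to heavy-tailed, weak-signal settings, not to every dataset.

What the generator does *not* emulate: binary perturbation fingerprints
(features are Gaussian), duplicated compounds, correlated targets, or any
assay chemistry. Conclusions from the synthetic tests transfer to real
data only insofar as those data share the band-structured, heavy-tailed
response shape.

With `n_regimes=1` the generator reduces to a single homoscedastic linear
model (and with `noise_sd=0` an OLS oracle is exact on test data) — both
are test anchors.

## Problem sizes in the shipped tests

Unit tests run on 90-sample fixtures with 15-tree forests — they check
wiring and contracts, not accuracy. Trend tests and the acceptance script
use the reference conditions (700/300, p=50, 2 targets) with 200-tree
forests and 20 seeds, sizes chosen as the smallest at which the
qualitative trends are stable from run to run; the library default stays
at 1000 trees.

## Known limitations

- Under the random discretizer the one-vs-rest classes are statistically
  identical by construction, so a calibrated classifier's positive
  probability concentrates at the trained class prior; at the 0.5
  threshold (after balancing) roughly half of all samples are accepted
  and per-bin recall hovers near 0.5. Classifier reports on random bins
  therefore measure label noise, not skill, and settings in which such
  classifiers accept essentially every sample are not reproduced by any
  standard probability threshold on continuous, duplicate-free features.
- The percentage-difference statistic explodes when base R² is near zero;
  it is reported because it is the field's headline convention, with the
  instability flagged.
- SMOTE operates on raw feature scales; heterogeneous features should be
  standardized first.
- Supervised or adaptive discretization, stacked meta-learning,
  multi-target coupling and cross-validated hyperparameter search are out
  of scope; multi-target inputs are handled by fitting one independent
  model per target.
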