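# Methods

## Synthetic cohort model

Each subject is a T×R matrix of ROI time courses (defaults R = 30,
T = 140, TR = 3 s). Columns start as independent Gaussian white noise,
Fourier-masked to the resting-state band [0.01, 0.08] Hz (DC removed) and
standardized — exact band control with no filter roll-off. Couplings are
then injected in order:

* linear edge (i, j, s): `col_j <- std(col_j + s * col_i)`;
* non-linear edge (i, j, f, s): `col_j <- std(col_j + s * std(bandmask(f(col_i))))`,
  f ∈ {x², sin(2πx), |x|}.

The transform output is masked back to the pass band before injection.
Two reasons. First, a pointwise non-linearity creates harmonics outside
the band, and any band-pass preprocessing applied to real recordings
would remove them; keeping them would also hand the classifier a spectral
(linear-statistics) cue that has nothing to do with non-linear dependence —
early versions of the generator leaked exactly that cue into the
PCC pipeline. Second, it makes the package-level guarantee unconditional:
less than 1 % of every emitted column's power lies outside the band. The
cost is that the injected component is no longer a pointwise function of
the source (it is temporally smeared), so MIC values for coupled pairs are
lower than the textbook noiseless case: a quadratic edge of strength 5 at
T = 500 yields MIC ≈ 0.28 against an independence level ≈ 0.1, rather than
the ≈ 0.77 an unfiltered pointwise injection would give.

Standardizing f(col_i) before injection makes `s` a unit-variance effect
size comparable across transforms. In the default contrast cohort every
non-linear edge has its **own** source ROI: two targets driven by one
shared source would be mutually correlated through their (even)
transforms, leaking a Pearson-visible group difference and defeating the
purpose of a purely non-linear contrast.

Default study conditions (`default_contrast_spec`): 20 subjects per group,
5 linear edges at strength 0.8 in every group (a backbone that carries no
group information), 10 non-linear edges with severity-graded strengths
CN 0.4 / MCI 1.0 / AD 1.6. The strengths were chosen so the coupled
component is comparable to the unit-variance noise floor — detectable by
MIC at T = 140 but not saturated. Per-subject variation comes only from
the noise realization (independent child seed streams of one seed
sequence, so cohorts are bit-reproducible and order-insensitive).

What the generator does **not** emulate: hemodynamic response convolution,
scanner drift and motion artifacts, spatial autocorrelation between
parcels, site/protocol heterogeneity, and realistic whole-brain covariance
structure. Passing tests on this generator therefore demonstrate that the
estimators and the pipeline recover the dependence structure they are
designed for — not that comparable accuracies would be reached on clinical
data.

## Dependence measures

**Pearson** uses the population (divisor n) convention in both numerator
and denominator. Zero-variance input is a hard error, never a silent 0.

**MIC.** Both series are rank-transformed (average ranks on ties), which
makes the estimator exactly invariant under strictly increasing transforms
and makes mass-equal binning well defined. Admissible grids satisfy
`nA * nB < B(n)` with `B(n) = max(ceil(n^0.6), 5)`; the 0.6 exponent is
the MINE family's published default, and the floor of 5 keeps the minimal
2×2 grid admissible at very small n (without it no grid at all is
admissible for n ≤ 10). For each admissible (nA, nB) and each axis
orientation, one axis is partitioned into nA mass-equal bins and the other
axis is optimized by dynamic programming over candidate cut positions at
data gaps; the per-bin objective decomposes additively, so one DP sweep
yields the best partition for every row count at most nB (refining a
partition never lowers MI). Mutual information is in bits (log base 2)
and each entry is normalized by `log2 min(nA, nB)`; floating-point
overshoot above 1 is clamped. Candidate cuts are capped at 64 mass-equal
positions (MINE-style clump coarsening); at n ≤ 12 all gaps are below the
cap, so small-n validation is exact. The DP kernel is JIT-compiled with
numba (~3 ms per pair at n = 140), which is what makes R = 30 cohort-scale
matrices (435 pairs/subject) affordable.

Two independent validation routes exist: `mic(..., method="exhaustive")`
enumerates every admissible cut combination through the production
histogram/MI code, and `exhaustive_mic_oracle` re-implements the same
definition with plain-Python dictionaries and entropy sums. Tests require
heuristic ≤ oracle always (the heuristic search space is a subset) and
exhaustive = oracle to 1e-9.

**eMIC** is literally `MIC - rho²`, not clamped: finite-sample MIC can dip
below rho², so slightly negative values are legitimate and documented
(range [-1, 1]). Diagonal conventions: PCC 1, MIC 1, eMIC 0; diagonals are
excluded from features and graphs.

## Graphs and embeddings

Edge weights are measure-aware: |PCC| (anticorrelation is strong
connectivity for a walk), MIC as-is, and eMIC clamped at 0 **at the graph
stage only** — estimator output is never altered. Optional proportional
thresholding keeps the top fraction of edges by weight (ties broken
lexicographically); a node isolated by thresholding is reattached through
its strongest edge. Walks require a connected graph and fail loudly
otherwise.

node2vec walks are second-order: the unnormalized probability of stepping
v→x given the previous node t is `w(v,x) * alpha`, alpha = 1/p if x = t,
1 if x neighbors t, 1/q otherwise; p = q = 1 (the default, reducing to
weighted first-order walks) takes a fast path. Embeddings are trained by
skip-gram with negative sampling (unigram^0.75 noise distribution, fixed
context window) implemented as batched SGD in numpy. With a vocabulary of
only R nodes, each node collects hundreds of pair-gradients per batch;
applying their *sum* at the usual per-pair learning rate diverges, so the
trainer applies the per-index *mean* gradient with a linearly decaying
learning rate (default 0.1, tuned for this update rule — at 5 epochs it
fully separates a two-clique benchmark on every tested seed). Training is
single-threaded and bit-deterministic given the seed; every subject uses
the same seed, so identical graphs produce identical feature vectors and
feature differences reflect graph differences only.

**Subject features: default is the flattened FC upper triangle,** not the
node2vec concatenation. Measured on the default study conditions
(R = 30, T = 140, 20+20 subjects), concatenated node-embedding coordinates
lose the group signal: the between-group difference lives in the relative
geometry of specific node pairs, while each raw coordinate's group shift is
buried under walk/SGD sampling noise (eMIC-over-PCC accuracy gain ≈ 0.03,
versus ≈ 0.4 for flattened-FC features; increasing walks per node did not
close the gap). Flattened FC preserves the measures' information exactly
and keeps the measure comparison interpretable, so it is the default;
node2vec features remain fully implemented, tested on designed graphs
(walk law, community separation, determinism) and selectable via
`feature_mode = node2vec` for larger cohorts where embedding averaging is
affordable.

## Multilayer ELM

As specified by the algorithm this classifier follows, every hidden layer
is computed **from the input**: `H_l = g([X_std, 1] W_l)` with W_l drawn
i.i.d. uniform [-1, 1] from the seeded generator, H the column
concatenation of all layers. The conventional stacked composition
(`layer_mode = "stacked"`, each layer fed the previous output) is provided
for comparison; the package takes no position on which variant a given
published accuracy used. "1000 hidden units" is interpreted as 1000 total
neurons split over 3 layers (334/333/333) — a thousand *layers* would be
inconsistent with a one-shot pseudoinverse solve. Output weights:
`beta = pinv(H) Y` at ridge_lambda = 0 (the literal Moore–Penrose
solution, minimum-norm least squares), else
`beta = (H'H + lambda I)^{-1} H'Y`; the default lambda = 1e-6 is purely
numerical stabilization (the ridge path converges to the pseudoinverse
solution as lambda → 0, tested at 1e-12). Inputs are standardized by
training-fold statistics stored in the model; prediction is argmax over
class scores with ties resolved to the lowest class index. There is no
epoch parameter anywhere: training is a single factorization.

## Evaluation protocol

Stratified k-fold (default 10) with shuffling, seeded. Feature selection
(top-k by absolute Welch t-statistic, ties to the lower index — chosen
because no ranking statistic is canonical for "top-ranked features") and
feature standardization are computed on the training fold only; a canary
test verifies a test-fold-indicator feature cannot inflate accuracy.
Metrics use the standard definitions — sensitivity TP/(TP+FN),
specificity TN/(TN+FP) — with the positive class fixed to the
more-impaired group (CN < MCI < AD), so sensitivity reads "impaired
correctly detected". An `as_printed` mode computes the alternative forms
in which both rates share the full denominator TP+TN+FP+FN (making
sensitivity + specificity equal accuracy); it exists for auditability
against sources that print those forms and is never used for reporting.
Metrics are macro-averaged over folds; a fold with no positives (or no
negatives) is excluded from the affected rate with a logged warning.
Accuracy on balanced cohorts differs from pooled-confusion accuracy by
at most the fold-size granularity (tested ≤ 0.02).

## Pipeline and reproducibility

One INI config drives generate → fc → embed → classify. Unknown keys are
rejected by name; defaults are filled and echoed. Every stage derives its
seed from the single top-level seed via CRC-32 of the stage name, so
stages re-run in isolation reproduce the full run. Report JSON carries no
timestamps (timings go to run.log); re-running an identical config is
byte-identical across all numeric artifacts — cohort TSVs, FC matrices,
features, reports — which the test suite asserts.

## Problem sizes and numerical choices

Tests and the acceptance script run the study at R = 30, T = 140, 20
subjects per group — the package's chosen desk scale; R is configurable up
to a 116-region atlas, with MIC cost growing as R². Degenerate inputs
(constant series/columns, zero-variance features, single-class folds) are
hard errors naming the offender. MIC uses float64 throughout; counts in
the DP are exact integers in float representation.

## Known limitations

* MIC's grid search is the standard approximation, not the exhaustive
  optimum; only n ≤ 20 admits exact search.
* The eMIC null level at T = 140 is ≈ 0.18 (MIC's positive bias minus a
  small rho² term), so raw eMIC values are not comparable across very
  different T without recalibration.
* node2vec subject features are noise-limited at desk scale (see above).
* The generator's group contrast is idealized: effect sizes are free
  parameters of the synthetic model, not estimates of clinical effect
  sizes, and no claim about real-cohort accuracy follows from them.
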