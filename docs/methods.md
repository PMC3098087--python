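# Methods

This note documents the statistical model behind `imbsim`, the choices made
where the design was genuinely open, and what the package's tests do and do
not establish.

## Generating model

Each simulated dataset has `n` samples in two classes and `p` independent
Gaussian variables with common standard deviation σ (default 1).

- **Null case** (`p_de = 0` or `mu2 = 0`): every variable is N(0, σ²) in
  both classes. Any classifier is uninformative by construction; its
  expected behaviour (mean PA = 0.5 on a balanced test set, PA₁ = 1 − PA₂,
  PV₁ = κ₁, AUC = 0.5) is the calibration baseline the test suite checks.
- **Alternative case**: the first `p_de` variables ("non-null", flagged in
  `truth_mask`) are N(μ⁽²⁾, σ²) for Class-2 samples and N(0, σ²) otherwise.

Training and test sets are generated **directly with their target class
counts** `n₁ = round(k1·n)` (round-half-up, so the .5 boundary favours
Class 1; `k1train = 0.05, n = 80` gives the 4-vs-76 design). Generating a
single pool and splitting it would be distributionally identical under
independence; direct generation controls both imbalances exactly and keeps
every replication's sample sizes constant. Class counts that round to zero
are rejected at configuration time.

Reproducibility uses a counter-based stream split:
`SeedSequence(master_seed, spawn_key=(replication, stream))`, with stream 0
for data generation and stream 1 for correction/classifier randomness.
Replications are therefore independent, order-insensitive and
parallelizable, and adding a consumer of randomness to one stage never
perturbs another.

### Microarray-shaped fixture

`make_microarray_fixture` produces a **synthetic** dataset with the shape of
a two-class breast-cancer cDNA study (99 samples × 7650 probes, 34 vs 65 by
default): independent Gaussians, an optional equicorrelated block structure,
`min(100, p/2)` informative variables shifted by 0.8 by default, and
optional injected missing values that are replaced with 0 on ingestion (the
usual convention for missing log-expression values). It supports
application-style experiments (stratified, disjoint train/test subsampling
at chosen class counts) but makes no attempt to model probe-level microarray
noise; conclusions about real data must come from real data.

## Pipeline order

Per replication: simulate → normalize (train and test **separately**) →
apply the imbalance correction to the training set → select variables on
the corrected training set → fit → predict the test set. Two points are
deliberate:

- normalization parameters are never shared between train and test, so the
  test set cannot leak into training (and vice versa);
- selection happens *after* correction. For MultDS the selection runs
  inside every member resample. (The alternative — selecting once on the
  full imbalanced set and then down-sizing — re-introduces the selection
  bias and destroys the correction's benefit: in our runs it leaves the
  minority accuracy near 0.09 instead of 0.70.)

## Variable selection

Default ranking is the pooled-variance two-sample |t|; variables with zero
pooled variance score 0 (they cannot be informative under the model, and
this avoids an arbitrary epsilon). Ties in `select_top` break toward the
lowest index for determinism. Welch t, Wilcoxon rank-sum (midranks, score
|U − n₁n₂/2|) and fold change are provided behind the same interface as
commonly used alternates; all reproduce the same qualitative
selection-bias behaviour.

## Classifiers

All from-scratch classifiers share the conventions: labels 1/2, continuous
score oriented so larger ⇒ Class 1, discriminant ties assigned to Class 1
(the "≤" rule).

- **k-NN**: Euclidean distance, odd k ∈ {1, 3, 5} (vote ties impossible),
  exact distance ties to the lowest training index; score = fraction of
  neighbours in Class 1.
- **DLDA/DQDA**: closed-form diagonal discriminants; DQDA adds per-class
  variances and their log terms. Zero-variance variables are dropped at fit
  time with a warning rather than epsilon-padded, keeping the formulas
  literal.
- **PAM** (nearest shrunken centroids): class centroids standardized by
  `m_k (s_g + s₀)` with `s_g` the pooled within-class SD, `s₀ = median(s_g)`
  and `m_k = √(1/n_k − 1/n)`, soft-thresholded toward the overall centroid,
  plus a `−2 log π_k` prior term with π_k the training proportions. The
  threshold Δ scans 30 evenly spaced values from 0 to the smallest Δ that
  zeroes every difference, taking the **largest** Δ with minimal training
  misclassifications. (The m_k convention provably cancels out of this
  training-error-selected rule: rescaling m_k rescales the standardized
  differences and the grid by the same factor.)
- **PLR**: ridge-penalized logistic regression minimizing the penalized
  negative log-likelihood with unpenalized intercept, λ = 1 by default
  (larger λ degrades highly imbalanced fits; cross-validated selection is
  out of scope). Damped Newton–Raphson to gradient norm < 1e-8 (≤ 100
  iterations; when the objective plateaus at floating-point resolution the
  optimum is accepted if the gradient norm is < 1e-6, otherwise a
  `ConvergenceError` with iteration diagnostics is raised). Classification
  at p̂ > 0.5, or p̂ > k1train for `plr_thr`; exact ties broken at random.
- **RF / SVM**: adapters over scikit-learn. RF: 500 unpruned trees,
  `⌊√p⌋` candidate variables per split (`rf_mtry="all"` exposes the
  all-variables alternative), class weights = training proportions, score =
  fraction of trees voting Class 1, cutoff 0.5 or k1train (`rf_thr`). SVM:
  linear kernel, per-class weights = training proportions, no internal
  feature scaling; score = Class-1-oriented decision value. Exact numerical
  agreement with other backends is not claimed for these two — only
  statistical agreement.

## Corrections

Over-sampling duplicates `max − min` randomly chosen minority samples, with
replacement whenever the deficit exceeds the minority size (e.g. 72
duplicates from 4 originals — the only consistent reading of the size
formula). Down-sizing removes random majority samples without replacement
and requires ≥ 2 minority samples (variance estimates are undefined below).
MultDS fits B = 101 (odd, so majority votes cannot tie) down-sized members,
each with its own selection; its continuous score is the vote fraction —
the method itself defines only hard votes, and the vote fraction is the
natural score for AUC.

## Evaluation

PA decomposes exactly as `PA = PA₁·k1test + PA₂·k2test` when the weights
are the empirical test proportions (asserted to 1e-12 in tests). PVs use an
assumed population prevalence κ₁, defaulting to k1train (prevalence matched
between training set and population); a zero denominator yields NaN, not 0.
AUC is the rank/concordance form with midrank tie correction, computed from
continuous scores (hard labels would pin the ROC to two points). Prediction
intervals are empirical 2.5th/97.5th percentiles with linear interpolation;
NaN replications are dropped, and fewer than 40 replications triggers a
warning.

## Problem sizes and replication counts

The full-scale design repeats every scenario 1000 times; the package
defaults to R = 200 per scenario so every preset runs in desk-scale minutes,
and R is a parameter everywhere (CLI flag `--reps`). The acceptance script
uses R = 200–500 per scenario (matching the binomial noise of the
tolerances it is checked against); the two down-sizing acceptance tests run
at the full R = 1000 because their expected values sit within ~0.01 of a
tolerance edge, where a reduced-R estimate would be dominated by Monte-Carlo
noise.

## Known limitations

- The generator draws independent Gaussians; real expression data are
  correlated, heavier-tailed and batch-structured. Passing tests establish
  the pipeline's behaviour under the stated model, not performance claims
  for any particular real dataset.
- Only two-class problems are supported; multiclass discriminants, kernel
  SVMs and synthetic minority generation (SMOTE-style) are out of scope.
- Our PAM, although verified against the soft-threshold algebra by hand
  computation, yields a down-sized minority accuracy of ≈ 0.86 in the
  k1train = 0.2 alternative-case benchmark, a few points above the ≈ 0.8
  reported historically for that setting with a different backend; the
  discrepancy is documented in the acceptance test rather than hidden.
- PLR fixes λ = 1; no penalty selection is performed.
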