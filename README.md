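# imbsim

Simulation pipeline for studying **class prediction on high-dimensional
class-imbalanced data** — the common situation in gene-expression and other
omics studies where the number of variables *p* vastly exceeds the number of
samples *n*, and the two outcome classes are unequally represented.

Classifiers trained on imbalanced training sets tend to assign new samples
to the majority class, and with high-dimensional data the usual variable
selection step makes this worse: sampling variability is larger in the
minority class, so the top-ranked variables are exactly those whose minority
means deviate most from their true values. `imbsim` provides the machinery
to quantify these effects and the standard remedies, for both simulated and
user-supplied expression matrices.

## What's in the box

- **Data generator** — two-class Gaussian design with *p* independent
  variables; under the *null case* every variable is N(0, σ²) in both
  classes, under the *alternative case* `p_DE` variables have mean μ⁽²⁾ in
  Class 2. Training and test sets are generated with exact class counts
  `round(k1·n)`. A microarray-shaped synthetic fixture (99 × 7650 by
  default) and stratified subsampling support application-style designs.
- **Normalization** — raw values, per-sample (row) mean-centering, or
  per-variable (column) mean-centering; always computed separately on
  training and test sets.
- **Variable selection** — top-*G* ranking by the pooled-variance two-sample
  *t* statistic (default), Welch *t*, Wilcoxon rank-sum, or fold change;
  always computed on the training set only. `G = p` disables selection.
- **Classifiers** — *k*-NN (k = 1, 3, 5), diagonal linear and quadratic
  discriminant analysis (DLDA/DQDA), nearest shrunken centroids (PAM) with
  training-error threshold selection, ridge-penalized logistic regression
  (PLR, λ = 1, Newton–Raphson) — all implemented from their closed forms —
  plus random forest and linear SVM adapters (class weights/priors equal to
  training class proportions, no internal scaling). `plr_thr` / `rf_thr`
  classify at the threshold `k1train` instead of 0.5.
- **Imbalance corrections** — over-sampling (duplicate minority to
  `2·max(n₁,n₂)`), down-sizing (discard majority to `2·min(n₁,n₂)`), and
  multiple down-sizing (MultDS): B = 101 down-sized sets, each with its own
  embedded variable selection and classifier, combined by majority vote.
- **Evaluation** — per replication: overall predictive accuracy
  `PA = PA₁·k1test + PA₂·k2test`, class-specific PA₁ (sensitivity) and PA₂
  (specificity), predictive values
  `PV₁ = κ₁PA₁ / (κ₁PA₁ + (1−κ₁)(1−PA₂))` (and symmetrically PV₂) under an
  assumed population prevalence κ₁, and rank-form AUC with tie correction;
  across replications: means and 95% prediction intervals
  (2.5th–97.5th percentiles).

## Worked example

Train DLDA on an 8-vs-72 imbalanced training set (p = 1000 variables, 20 of
them shifted by μ⁽²⁾ = 1 in Class 2, top 40 selected by |t|), evaluate on a
balanced 20-sample test set, 200 replications:

```python
from imbsim import ScenarioConfig, run_scenario

for corr in ("none", "downsize"):
    cfg = ScenarioConfig(p=1000, p_de=20, mu2=1.0, G=40, k1train=0.1,
                         k1test=0.5, classifier="dlda", correction=corr,
                         replications=200, master_seed=42)
    print(corr)
    print(run_scenario(cfg).summary().to_string(index=False))
```

```
none
metric     mean  pi_low  pi_high
    PA 0.650250 0.50000 0.850000
   PA1 0.305000 0.00000 0.700000
   PA2 0.995500 0.90000 1.000000
   PV1 0.967478 0.25000 1.000000
   PV2 0.928279 0.90000 0.967742
   AUC 0.934400 0.78975 1.000000

downsize
metric     mean   pi_low  pi_high
    PA 0.695250 0.400000  0.90125
   PA1 0.686500 0.300000  1.00000
   PA2 0.704000 0.300000  1.00000
   PV1 0.274824 0.076923  1.00000
   PV2 0.950637 0.865179  1.00000
   AUC 0.773600 0.499750  0.98025
```

Without correction the classifier is strongly biased toward the majority
class (mean PA₁ = 0.31 vs PA₂ = 1.00): most minority test samples are
misclassified even though the classes genuinely differ. Down-sizing the
training set to 8 balanced samples per class equalizes the class-specific
accuracies (0.69 vs 0.70) at the cost of using fewer samples; note PV₁
drops because the majority-class accuracy is no longer ≈ 1.

## Command line

```sh
imbsim simulate --p 1000 --p-de 20 --mu2 1 --k1train 0.1 --seed 3 --out data/
imbsim run --preset fig5 --reps 200 --seed 42 --out runs/fig5/
imbsim run --config scenario.yaml --reps 500 --seed 1 --out runs/custom/
imbsim report --in runs/fig5/ --plot
```

`run` accepts built-in presets (`fig1`…`fig5`) covering the canonical
scenario grids — null case without/with selection, alternative case over
p ∈ {40, 1000, 10000}, the μ⁽²⁾ sweep with both centering variants, and the
four-way correction comparison — and writes tidy per-replication results
(`replications.csv`), across-replication means (`summary.csv`) and run
metadata (seed, config hash, version).

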