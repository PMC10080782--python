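# Methods

## Model and test

Let X = (X₁, …, X_p) be mixed-type clinical features and Z ∈ {0, 1} a
binary outcome with π(x) = Pr(Z = 1 | X = x). The package estimates π
with an arbitrary probability estimator and tests, per feature j, the
null hypothesis that X_j contributes nothing to π conditional on the
other features.

**Importance score.** X^(j) denotes X with its j-th feature replaced by
a uniform random permutation of its own values. The per-subject term

Δ_ij = Z_i log(π̂(X_i)/π̂(X_i^(j))) + (1−Z_i) log((1−π̂(X_i))/(1−π̂(X_i^(j))))

has expectation (over Z given X, with the true π plugged in) equal to
KL(Bern(π(X_i)) ‖ Bern(π(X_i^(j)))) ≥ 0, with equality iff the
permutation leaves π unchanged — i.e. iff X_j is conditionally
irrelevant. This identity is verified by enumeration in the test suite.

**Cross-fitting.** To stop π̂'s in-sample optimism from inflating the
terms, the rows are split into stratified folds (default 5); π̂ is fit
on each fold's training complement and the terms are evaluated on the
fold's validation rows only. Per fold and feature, the terms are
averaged over `n_permutations` independent block permutations (default
100 as a library default; a single permutation reproduces the plain
single-shuffle estimator). Terms are pooled across folds.

**Test statistic.** With n_V pooled terms, Δ̂ = mean(Δ_ij), the
variance of the mean is estimated as the per-term sample variance
(1/n_V)Σ(Δ_ij − Δ̂)² divided again by n_V, and δ = Δ̂/SE is referred to
the one-sided upper standard-normal tail. One-sided is the natural
choice because importance is nonnegative in expectation under the
alternative. Degenerate zero-variance inputs resolve by the sign of Δ̂
(positive → p = 0, negative → p = 1, exactly zero → δ = 0, p = 0.5,
matching the forced-identity-permutation oracle). A feature constant in
every validation fold is reported with Δ̂ = 0, p = 1 and a `degenerate`
flag rather than a spurious test.

**Block permutation.** A categorical feature with m levels occupies
m − 1 reference-coded columns; permutation moves the whole block under
one shared row permutation so each clinical feature gets exactly one
test. The reference level is the first declared level; reference coding
(rather than full one-hot) avoids exact intercept collinearity for the
logistic baseline. The test itself is encoding-agnostic because it
permutes at the feature-block level.

**Multiplicity.** Default is no adjustment (significance declared at
raw p ≤ α = 0.05); Benjamini–Hochberg is available behind a config
flag.

## Stable DNN ensemble

A single SGD-trained network is sensitive to its random initialization.
The stable ensemble (a) trains K networks on bootstrap resamples
(default K = 100; members differ only by resample and seed), (b) scores
each member on its out-of-bag rows by λ_k — the mean OOB log-likelihood
gain over the constant predictor equal to the member's own OOB mean, so
λ = 0 for an uninformative member and λ < 0 for an anti-predictive one —
and (c) keeps the top-λ prefix whose averaged prediction minimizes the
training cross-entropy (ties resolve to the smallest prefix). Members
whose bootstrap bag contains a single outcome class are skipped with a
warning; an empty-OOB draw is redrawn. The per-member network is a
multilayer perceptron (ReLU hidden layers, logistic output) trained by
mini-batch SGD with an adaptive learning-rate schedule via
scikit-learn; the default architecture is (50, 40, 30, 20) hidden units
with no dropout. Default optimizer settings (100 epochs, batch 32,
initial rate 10⁻³) are library defaults, configurable. Probabilities
are clipped into [ε, 1−ε] with ε = 10⁻⁶ everywhere a log is taken,
because comparator learners can emit exact 0/1.

## Comparators

Random forest (1000 trees, minimum terminal node size 3, 4 candidate
variables per split), XGBoost (5 boosting iterations), an RBF-kernel SVM
with sigmoid-calibrated probabilities, and an unpenalized logistic
baseline, all behind one `fit`/`predict_probability` contract; a
`tune_by_cv` helper picks grid points by stratified-CV cross-entropy on
the training data only. These are adapters over scikit-learn/xgboost,
not re-implementations: the contribution under test is the scoring and
permutation machinery, which is estimator-agnostic.

## Evaluation protocol

Stratified 10-fold cross-validation produces out-of-fold probabilities
(every row predicted once by a model that never saw it; continuous
columns are re-standardized per training fold — standardization is
affine-equivariant, so this equals refitting the encoder on raw
values). Classification uses the strict 0.5 cutoff (π̂ = 0.5 → class
0). Metrics: accuracy, rank-method AUC, PR-AUC as average precision
with the positive (minority) class as the target, sensitivity,
specificity; 95% intervals by stratified bootstrap (2000 resamples,
percentile, widened if needed to contain the point estimate — the
interval method is a package choice, documented here because no single
convention is canonical). The restricted-arm contrast (all features vs
the model's own significant set) reuses the same folds; an empty
significant set falls back to a flagged prevalence-predicting stub.
Feature selection is not repeated within folds, so the contrast carries
mild selection optimism (stated in the README).

## Synthetic cohort generator

The generator defines the study conditions for every simulation in the
package. It emulates: the 24-feature schema (one continuous age; the
13-level injury mechanism; linked "Not applicable" levels — hematoma
size is NA iff location is NA iff no hematoma was raised, seizure
duration NA iff no seizure, the trauma-region items NA iff no
supra-clavicular trauma); age from a gamma distribution matched to mean
9.3 / SD 6.75 months and rejected onto [0, 24) (the gamma family is a
package choice; only the two moments are constrained by the cohort);
categorical marginals from the published baseline table where available
and realistic values elsewhere; and outcome prevalence 8.5%, hit by
bisecting the intercept on a fixed 100 000-row calibration sample to
±0.002 (the intercept is a deterministic property of the configuration,
shared across cohort seeds).

The default risk surface is nonlinear and interactive on the logit
scale: a smooth non-monotone age bump (height 1.1 at 3 months, width
3.5, slope −0.03), main effects for acting-normally, altered mental
status, injury mechanism, hematoma location and size, and a
younger-age × non-frontal-hematoma interaction (0.06·(12 − age) for
occipital/parietal-temporal locations). All remaining features are
null by construction: permuting any of them leaves the true π unchanged
row-wise, which is what makes the type-I-error studies honest.

What the generator does **not** emulate: cross-feature correlation
beyond the structural NA links (deliberate — correlated nulls would no
longer be conditionally independent of the outcome), measurement error,
missingness mechanisms, and site effects. Passing simulations therefore
demonstrate calibration and power under independent features with a
known smooth risk surface, not under every real-data pathology.

**Structural-alias caveat.** Features deterministically tied to a
signal feature (e.g. the raised-hematoma flag, which equals
"hematoma location ≠ NA") can legitimately receive small p-values: the
permutation breaks the deterministic link, and no conditional-on-the-
rest null holds for an alias of a signal. This is a property of
permutation importance under structural constraints, not a calibration
failure; the type-I-error guarantee applies to features that are
genuinely independent of the outcome and of the signal set.

## Simulation study sizes

The operating-characteristic studies (tests and `scripts/acceptance.py`)
use a compact six-feature schema — one planted binary signal
(prevalence 0.3, logit effect 2.0 by default), one continuous null and
four categorical nulls — at n = 1500 and prevalence 0.085, with the
logistic factory, 5 cross-fitting folds and 10 permutations per fold:
200 replicates for type-I error, 100 for power, 50 per effect size for
δ monotonicity, 50 for the ensemble-filter study. These sizes are the
package's chosen study design; the machinery is identical at any scale.

## Numerical choices and determinism

Probability clipping ε = 10⁻⁶; λ-ranking ties break by member index;
ensemble-size ties break to the smallest prefix; the 0.5 cutoff assigns
the boundary to class 0; the age filter is strictly `< 24` months.
One master seed fans out via CRC-32 keyed derivation
(`derive_seed(master, *keys)`) to fold assignment, per-fold estimator
seeds, per-feature permutation streams and bootstrap draws — keyed on
content, so adding a feature leaves other features' permutation streams
untouched, and the whole pipeline is byte-reproducible (checked by
re-running it and comparing CSV serializations).

## Known limitations

* The Z-test relies on approximate normality of the pooled mean term;
  at very small n_V or for features with extremely rare informative
  levels the normal tail is an approximation.
* Conditional importance shrinks under feature duplication or strong
  redundancy (demonstrated in the tests); a feature can be marginally
  predictive yet conditionally insignificant.
* The structural-alias effect above: significance can spread across
  deterministically linked features.
* The two-stage evaluation contrast is descriptive, not selection-
  corrected.
* Binary outcomes only; no conditional-permutation or knockoff
  variants.
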