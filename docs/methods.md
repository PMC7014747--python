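# Methods

## Problem and data model

The package predicts, from preoperative information only, whether a
patient with advanced (FIGO III–IV) epithelial ovarian cancer will achieve
*optimal* primary cytoreduction, defined as zero residual tumor. The
positive class throughout is **suboptimal** cytoreduction — the event the
models try to flag. A cohort is a complete-case table of one row per
patient: age (years), FIGO stage (III/IV), tumor grade (1–3), histology
(serous/other), preoperative serum CA125 (U/ml) and HE4 (pmol/L), ECOG
performance status (0–2), ASA class (1, 2, ≥3 collapsed to one `3plus`
level), and the surgical outcome. Validation is strict: markers must be
positive, age in [18, 100], stage restricted to III/IV, and no missing
fields — records failing any rule are rejected with the row and field
named, mirroring the complete-case design of the reference analysis.

## Descriptive comparisons

`summarize_cohort` reproduces the usual outcome-stratified
characteristics table. Continuous variables are compared with a
two-sample *t*-test; the package default is **Welch** (unequal variances),
because the marker SDs differ between outcome groups by factors of ~3 and
because Welch applied to the reference HE4 group moments (419.96 ± 355.56,
n = 52 vs 997.44 ± 1050.33, n = 31) reproduces the reported p = 0.006; the
pooled Student flavor is available by option. Categorical variables use
Pearson χ² without continuity correction; when any expected cell count
falls below 5 a warning notes that the asymptotic p-value is approximate
(no automatic Fisher fallback). Sample SDs use the n − 1 denominator. A
`welch_t_from_moments` helper performs the summary-statistic path so group
moments alone suffice.

## Diagnostic machinery

Sensitivity, specificity, PPV, NPV and accuracy follow the standard 2×2
definitions with suboptimal as positive. A zero-denominator metric is
returned as `nan`, never coerced. Accuracy satisfies the identity
`acc = prev·sens + (1 − prev)·spec` exactly, which the suite checks
property-wise.

The empirical ROC is built from thresholds at every distinct score with
the rule `score ≥ cutoff → positive`; the AUC is the midrank Mann–Whitney
statistic (ties counted half), which equals the trapezoidal area of the
curve — the suite verifies both computations agree to 1e-12 and match
scikit-learn's `roc_auc_score` as an independent oracle. Cutoff selection
maximizes Youden's J over midpoints between consecutive distinct scores
(±∞ sentinels included), ties broken toward the lowest cutoff; a
closest-to-(0,1) criterion is selectable. The reference cutoffs — HE4
777.10 pmol/L, CA125 313.60 U/ml, age 68.5 years — are data-dependent
quantities of the unavailable real cohort and are therefore shipped as
fixed constants in `CutoffSpec`, not reproduction targets.

AUC uncertainty uses the Hanley–McNeil variance
`[A(1−A) + (n⁺−1)(Q1−A²) + (n⁻−1)(Q2−A²)]/(n⁺n⁻)` with `Q1 = A/(2−A)`,
`Q2 = 2A²/(1+A)`, a symmetric normal CI clipped to [0, 1]. Power against
the null AUC 0.5 is `Φ((A₁ − 0.5 − z_{1−α/2}·SE₀)/SE₁)` with SE₀/SE₁ the
Hanley–McNeil SEs at 0.5 and A₁; at A₁ = 0.73 with 31/52 group sizes and
α = 0.05 this evaluates to 0.9551, i.e. 96% when rounded. DeLong variance
and exact binomial CIs are deliberately out of scope.

## The PIV model

Each of the eight parameters is dichotomized by `CutoffSpec`. Boundary
conventions: CA125/HE4/ASA use ≥, age and ECOG use strict >. The positive
category for histology is **non-serous**: that direction is the one
consistent with the reference per-parameter diagnostic table (8/31
non-serous among suboptimal → sens 0.26; 45/52 serous among optimal →
spec 0.87), even though the reported multivariable fit points the other
way — the conflict is inherent to the source material and is resolved in
favor of the per-parameter table for the PIV path.

Two weighting rules are provided because the source material's selection
sentence (accuracy ≥ 75%, PPV ≥ 50%, NPV ≥ 50%) is not satisfiable by any
parameter's printed accuracy:

* `ppv_weighted` (default): every parameter is retained with weight 2 iff
  PPV ≥ 0.5, else 1. On the reference diagnostics this reproduces the
  printed point column (2,1,2,1,1,2,2,1) exactly, maximum score 12.
* `selected_only`: only parameters with PPV ≥ 0.5 and NPV ≥ 0.5 are kept,
  each at weight 2 — {age, histology, HE4, ECOG}, maximum score 8,
  matching the reported 0–8 score range.

The two readings cannot be reconciled (an all-parameter weighting yields a
theoretical maximum of 12, yet odd scores in the reported sweep rule out
the all-weights-2 variant); both are first-class, neither is forced. An
`accuracy_min` knob (default 0) restores the accuracy filter if wanted.
`threshold_sweep` evaluates `PIV ≥ t` for t = 1..max_score and enforces,
as a post-condition, that sensitivity is non-increasing and specificity
non-decreasing in t. `PIVClassifier` wraps the whole construction as an
sklearn estimator (`fit` → cutoffs, per-parameter diagnostics, weights;
`decision_function` → integer scores; `predict` at a configurable score
threshold, default 6).

## Logistic model

`IRLSLogisticRegression` fits by Newton–Raphson on the log-likelihood
(IRLS), starting from β = 0, converging when the largest absolute score
component falls below 1e-8 (max 50 iterations), with Wald SEs from the
inverse observed information. The log-likelihood path is stored and is
non-decreasing on every fit. Separation is an explicit error, never
silent garbage: a linear predictor exceeding |30| during iteration, a
singular information matrix, or all fitted probabilities saturating at
0/1 raises `SeparationError` (no Firth/penalized fallback by design).
The estimator agrees with statsmodels' `Logit` to 1e-8 on random designs
(test-suite oracle) and a single binary predictor reproduces the 2×2
cross-product OR and its Wald SE √(1/a+1/b+1/c+1/d).

The multivariable encoding is continuous age plus three indicators (CA125
≥ 313.60, HE4 ≥ 777.10, serous histology), outcome coded suboptimal = 1.
The frozen `PublishedModel` (0.12·age − 2.38·CA125⁺ − 1.86·HE4⁺ −
2.74·serous − 3.37) is applied verbatim as an external scorer: the
originally reported odds-ratio directions are mutually inconsistent
(e.g. age OR 0.10 univariately vs 1.13 in training; the serous direction
conflicts with the group frequencies), and whether "logit p" scores the
optimal or the suboptimal outcome was never fixed, so the package exposes
the raw linear predictor and inverse-logit probability without
sign-correcting. Consistency check kept: ln(1.13) rounds to the 0.12
age coefficient.

Split-sample validation draws a seeded random partition with
round-half-up training size (83 patients at fraction 43/83 → 43/40);
stratification by outcome is off by default, available by option.
Hosmer–Lemeshow groups observations by probability quantiles (ties kept
together; an error suggests fewer groups when distinct probabilities run
out), sums (O−E)²/E over groups and both outcome classes, and uses
df = groups − 2 (df 0 → statistic only, p undefined). Under a correctly
specified model its type-I error at α = 0.05 is within ±0.03 of nominal
over 500 simulated replicates (suite check — the test is known to be
approximate). Validation reports the AUC with Hanley–McNeil CI and the
Youden-optimal operating point.

## Synthetic cohorts

The generator emulates the 83-patient reference cohort: outcome
Bernoulli(31/83); age Gaussian per group (52.13 ± 9.81 optimal,
56.45 ± 11.24 suboptimal) truncated to [18, 90] by resampling (acceptance
> 99.9%, mean shift < 0.1%); CA125 and HE4 log-normal with parameters
moment-matched so the arithmetic group mean/SD equal the configured
values exactly (`σ² = ln(1+(sd/mean)²)`, `μ = ln(mean) − σ²/2`) — a
log-normal is used because the markers are positive with SD ≈ or > mean,
which rules out a Gaussian; a gamma family with the same two moments is
selectable since the true marker distribution is unverifiable.
Categorical covariates are drawn at the reference group frequencies; the
merged grade 1–2 band is split evenly between grades 1 and 2 (only
grade = 3 enters any rule). A single RNG stream draws records in order;
the seed and a config hash are recorded in the cohort provenance.

What the generator does **not** emulate: within-group covariate
correlation (covariates are independent given the outcome), so synthetic
cohorts cannot reproduce data-dependent quantities of the real cohort —
ROC cutoffs, marker AUCs (0.68/0.53), fitted ORs, the validation AUC or
the HL p-value. Passing tests therefore demonstrate correctness of the
machinery and calibration of the marginals, not clinical performance on
real patients.

## Pipeline and problem sizes

`run_full_analysis` chains load/simulate → summary → cutoffs (Youden on
CA125/HE4 from the data unless overridden) → parameter diagnostics → PIV
build and sweep → split → IRLS fit on the training half → evaluation of
both the refit and the published scorer on the validation half → power at
the refit AUC. One top-level seed expands into named sub-seeds
(generation, split) via SHA-256, so stages are independently
reproducible; rerunning a config renders byte-identical reports (floats
fixed at 4 decimals, stable ordering). Any stage failure aborts with the
stage name; partial reports are never written.

Default problem sizes: unit and property tests run on hand-built cohorts
(4–6 patients) and synthetic cohorts of 83–400; generator-calibration
checks use n = 200,000 (mean age ±0.15 y, marker means within 2%);
Monte-Carlo invariants use 100 replicates × n = 1000 (parameter recovery)
and 500 × n = 150 (HL type-I error). These sizes make the full suite run
in about a minute while keeping Monte-Carlo error well inside the stated
tolerances.

## Known limitations

* With 83 patients and 8 predictors, the n = 43 training half can be
  quasi-separated for some seeds; the pipeline then aborts with a clear
  error rather than reporting unstable estimates.
* Reported FIGO/grade comparison p-values (0.791/0.826) differ in the
  third decimal from textbook Pearson χ² on the same counts (0.793/0.825);
  the variant behind the originals is unknown and equality is not forced.
* The NPV/PPV column labels in the reported threshold-sweep table are
  transposed relative to the standard definitions used here (specificity
  1.0 with positive predictions forces PPV = 1, not NPV); the package
  keeps standard definitions.
* No missing-data handling, no penalized regression, no DeLong AUC
  comparison, no multiple-testing correction, no plotting.
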