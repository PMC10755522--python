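# Methods

## Overview

`braingap` implements brain-age-gap (BAG) analysis from regional
neuroimaging features. A regression model is trained on cognitively normal
(CN) subjects to predict chronological age from 90 atlas regions of one
modality at a time — gray-matter volume from T1-weighted MRI or SUVR from
FDG PET. The signed difference between (bias-corrected) predicted brain
age and chronological age is the BAG, in years; a positive BAG means the
brain looks older than it is. Downstream, BAG is related to cognitive
composites and amyloid/tau pathology markers through covariate-adjusted
partial correlations, compared across diagnostic strata, and used as a
single-feature predictor of two-year MCI-to-AD progression.

Because the clinical cohorts such analyses are normally run on are
access-restricted, the package ships a synthetic cohort generator whose
statistical structure matches the assumptions of every downstream stage.
All tests and the acceptance script run end-to-end on generated data.

## Brain age estimation

### Nested cross-validation

Training uses 5 outer and 5 inner folds (`BAEConfig`). Per outer fold:

1. **Outlier exclusion** on the outer-train portion only: a subject is
   excluded when any feature falls outside the per-feature Tukey fences
   `[Q1 − m·IQR, Q3 + m·IQR]` with multiplier `m = 6`. Test and
   validation subjects are never excluded. Zero-spread features use an
   absolute tolerance of 1e-12 so exact duplicates never self-flag.
2. **Model selection** by inner CV over every candidate
   (algorithm, hyperparameters) pair. Candidates are epsilon-SVR
   (kernels linear/RBF; C on a log grid 1e-3…1e3, 7 points;
   epsilon in {0.01, 0.1, 1}) and relevance vector regression
   (kernels linear/RBF). The pair with the lowest mean inner-validation
   MAE wins; ties break deterministically (SVR before RVR, then
   lexicographically smallest hyperparameters).
3. **Refit** of the winner on the full cleaned outer-train set,
   prediction of the outer-validation fold, and estimation of the
   bias-correction parameters from those held-out predictions.

Features are z-standardized inside every learner pipeline using the
statistics of the data the learner is fitted on, so no information leaks
from validation folds. Fold assignment is a seeded shuffled partition
without age stratification.

SVR fits are capped at 5000 solver iterations: with heavy
under-regularization on noisy standardized data, libsvm's working-set
solver converges extremely slowly, and the candidates that hit the cap
lose the inner CV regardless (on clean data they converge well before
it).

### Relevance vector regression

scikit-learn has no RVR, so `braingap.rvm.RVR` implements sparse Bayesian
kernel regression: a linear model over kernel basis functions centred on
the training points with an independent Gaussian prior precision per
weight, fitted by evidence maximisation. Precisions that diverge past 1e9
prune their basis functions. The noise precision is capped at 1e8 so that
noiseless training targets remain numerically solvable, and the posterior
Cholesky retries with escalating jitter before giving up. Convergence:
largest change in log prior precision below 1e-3, at most 300 sweeps.

### Bias correction

Brain-age predictions regress to the mean, producing a negative
correlation between uncorrected BAG and age. The correction fits, by OLS
on each fold's outer-validation predictions,

    BAG_raw = alpha * age + beta

and reports `corrected = raw − (alpha·age + beta)`. This parameterization
gives the identity `(alpha, beta) = (0, 0)` for a perfect predictor. It
removes the age *trend* of BAG but deliberately does not rescale
predictions; consequently a latent acceleration of `b` years in a test
cohort is recovered as roughly `s·b`, where `s < 1` is the regression
shrinkage slope. The offset-recovery test budgets for this attenuation
(a +2.5 y offset is expected back in the 2.0–3.0 y window). A
pooled-across-folds variant of the correction is available behind
`BAEConfig.pooled_bias` for sensitivity analysis.

### Inference modes

* `held_out` (training cohort only): each non-outlier subject receives
  the single prediction of the one fold model that never trained on it,
  corrected with that fold's parameters. Subjects flagged as outliers in
  any outer-train split receive no prediction.
* `ensemble_average` (external cohorts): every fold model predicts every
  subject; each prediction is corrected with its own fold's parameters
  and the five corrected estimates are averaged (correction before
  averaging).

Metrics reported per cohort: MAE (years), R², BAG range, mean BAG, n.

## Permutation importance

The importance of a region is the mean increase in MAE (years) when that
region's column is permuted across evaluation subjects. Each fold model
is evaluated on its own outer-validation subjects (never in-sample), with
10 repeats by default, and fold maps are averaged into one map per
modality. MAE — not R² drop — keeps importance in the same currency as
the accuracy results. With 90 weakly informative regions the per-region
deltas are small relative to permutation noise and can dip slightly
negative; only clearly informative regions stand out (the synthetic
single-signal tests use this). Maps are summarized as medians per lobe,
hemisphere, or lobe-by-hemisphere using the bundled atlas TSV, and
compared across modalities by Pearson correlation with a Fisher-z 95% CI.

## Association statistics

Partial correlations residualize both focal variables on the covariates
(age, sex as a male indicator, education in years, APOE-e4 carriership as
0/1) with an intercept, then correlate residuals. The method is chosen by
Shapiro–Wilk normality of the two focal variables at alpha 0.05 (Pearson
iff both pass); the Spearman variant rank-transforms the focal variables
(average ranks) and reuses the identical machinery, so Spearman-partial
equals Pearson-partial-on-ranks exactly. p-values use the t distribution
with n − k − 2 degrees of freedom, CIs are Fisher-z with standard error
1/sqrt(n − k − 3). Listwise deletion over the focal variables and
covariates; `n_used` is reported.

Group comparisons use a paired t-test for per-subject absolute errors
across modalities, Welch's t (with Welch–Satterthwaite dof) for
independent groups — group sizes and variances are routinely unequal
here — and ANCOVA (linear model, F on the binary group term) for
stable-vs-decliner BAG differences. Age joins the ANCOVA covariates only
when the corrected BAG still correlates with age at p < 0.05
(`age_covariate_rule`); the rule is executed, not hard-coded per
modality. Significance is tiered: p < 0.1 trend, p < 0.05 significant,
p < 0.05/m Bonferroni-significant within a family of m tests (cognition
m = 2, pathology m = 3 in the default pipeline).

Numerical degeneracies are resolved conservatively: residuals that are
pure round-off (sum of squares below 1e-20 of the raw sum of squares)
yield a zero correlation / zero F rather than noise ratios.

## Progression prediction

Stable-vs-decliner classification uses stratified 10-fold CV with a
single-feature logistic regression per predictor. In each training fold
the predictor is residualized on the covariates with a linear model fit
on that fold's *stable* subjects only; residuals are computed for all
subjects against this fit and standardized by the stable-group residual
SD. The logistic fit is effectively unpenalized (C = 1e8; a material
penalty would shrink predicted probabilities against the prevalence-based
cutoff). Fold AUCs use the Mann–Whitney tie-half convention; the mean
over folds is unweighted.

The classification cutoff is the a-priori probability: each training
fold's decliner prevalence, averaged over folds, with "decliner" called
at probability ≥ cutoff. Internal sensitivity/specificity come from
pooled validation-fold probabilities (no refit on all data). For external
validation the covariate residualization is refit on the external stable
group — covariate-predictor relationships are cohort-specific — while the
logistic coefficients (refit once on all internal rows) and the
internally derived mean cutoff are carried over unchanged. An AUC gate
(default 0.7) controls which predictors are carried to external
validation in the pipeline.

## Synthetic cohort generator

For subject i and region r:

    feature[i, r] = baseline[r] + slope[r]·(age_i + bag_i)
                    + confounding·covariates_i + N(0, noise_sd²)

with `bag_i ~ N(bag_shift_mean, bag_shift_sd)` the latent accelerated
aging offset in years. Making the offset additive on the age axis makes
"true BAG" well-defined, so parameter recovery is testable. Defaults:

* ages Uniform(60, 90) — the analysis is restricted to subjects over 60;
* 90 regions whose baselines and (negative) aging slopes are drawn once
  from a fixed generator per modality (MRI: volumes near 100 units,
  slopes −0.2 to −0.8 per year; FDG: SUVR near 1, slopes −0.002 to
  −0.008), so the profile is a property of the modality, not of the
  cohort seed;
* `noise_sd=None` calibrates the regional noise so the ideal linear age
  estimator has MAE 2.5 y (the accuracy regime of published elderly-cohort
  brain-age models): with i.i.d. noise, the GLS age estimate has SD
  sigma/||slope||, and MAE = sqrt(2/pi)·SD. `predicted_mae_floor` exposes
  this bound and the noisy-recovery test asserts the fitted model lands
  within 20% of it;
* sex ~ Bernoulli(0.5), education ~ N(16, 2.5) years clipped to [6, 24],
  APOE-e4 ~ Bernoulli(0.3), independent of age by default; optional
  confounding slopes push features around by sex/education/APOE so
  covariate-adjustment tests can distinguish confounded from clean
  regimes;
* cognitive composites = −coupling·bag + N(0, 0.95) (executive uses 0.8×
  the memory coupling); pathology markers move in the AD-typical
  directions per year of BAG (amyloid PET SUVR +0.015, CSF amyloid −25
  pg/mL, p-tau/amyloid ratio +0.004, all times `pathology_coupling`).
  The coupling magnitudes are not empirical estimates — no generative
  effect sizes exist to copy — they are chosen to give mid-sized,
  recoverable correlations at the default noise levels, and the tests
  check recovery against the analytically implied values rather than
  against the constants themselves;
* the decliner label is Bernoulli with log-odds
  `logit(base_rate) + k·bag_i`; `expected_decliner_rate` integrates this
  over the BAG distribution numerically for marginal checks;
* missingness is MCAR on the cognitive/pathology measures only, never on
  demographics.

What the generator does **not** emulate: site/scanner effects,
non-linear aging trajectories, longitudinal measurements, realistic
region-region covariance (noise is independent across regions), and
outcome-dependent missingness. Passing tests therefore certify the
estimation and statistical machinery, not performance on real scanner
data.

## Problem sizes and runtime choices

The test suite and acceptance script use cohorts of 100–400 subjects and
20 replicate seeds where an average over replicates is asserted; these
sizes keep Monte-Carlo error comfortably inside the asserted tolerances
while the full default 5×5 nested CV with the complete candidate grid
remains in use. The demo study is CN n=200 / SCD n=120 / MCI n=240 with a
decliner prevalence near 25%.

## Known limitations

* The bias correction removes the age trend but not shrinkage; recovered
  group offsets are attenuated by the regression slope (see above).
* RVR uses the classic iterative evidence maximisation, not the fast
  marginal-likelihood algorithm; it is adequate at n ≤ a few hundred.
* The atlas lobe/hemisphere map is an editable TSV in the
  automated-anatomic-labeling tradition; users with a different
  parcellation supply their own TSV (`load_atlas(path)`).
* FDG SUVR normalization requires an explicit reference region set; no
  default is assumed because conventions differ across PET pipelines.
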