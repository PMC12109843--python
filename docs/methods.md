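# Methods

## The clinical problem

Progressive pulmonary fibrosis (PPF) is the subset of interstitial lung
disease in which fibrosis keeps advancing despite treatment.  Two binary
questions drive the analysis: diagnosis (PPF vs nPPF) and prognosis (RAPID
vs SLOW progression).  The available evidence per patient is a small table
of pulmonary-function measures (Age, FVC%, FEV1%, DLCO, DLCO/VA),
bronchoalveolar-lavage (BAL) cell fractions (Macro%, Neu%, Lin%), and three
BAL exosomal biomarkers on the 2^-ddCT relative-expression scale (miR-21,
miR-92a, KL-6).  Cohorts of this kind are small — the reference setting is
39 patients, 19/20 split — so the pipeline is built around explicit
uncertainty quantification rather than point estimates.

## Model

The classifier is a Bernoulli GLM with logistic link on z-scored features:

    T | x ~ Bernoulli(p(x)),    p(x) = logistic(b0 + b . z)

with the increasing convention (positive coefficient -> higher probability
of the positive class: PPF for diagnosis, RAPID for prognosis).  Priors on
b0 and each coefficient are Student-t, preferred over normals for their
heavier tails.  Defaults: t(df=3, location=0, scale=2.5) per coefficient
and scale 5 for the intercept — a standard weakly-informative choice on
standardized predictors, fully configurable per feature.

### Posterior computation

Three engines, one contract (a fit is `converged` only if max split-R-hat
<= 1.01 and min bulk ESS >= 400, computed with ArviZ; non-convergence warns
and is recorded, never silently accepted):

* **`mcmc` (default)** — adaptive independence Metropolis-Hastings.  A
  pilot stage proposes from a multivariate Student-t (df 4) centred at the
  posterior mode (BFGS with analytic gradients) with 1.3^2 x the inverse-
  Hessian scale; the pilot draws then re-estimate the proposal's location
  and covariance — posteriors of near-separable small cohorts are skewed
  and wider than their local curvature suggests — and the main stage runs
  with that refined, fixed proposal, so the retained draws come from a
  valid non-adaptive MH chain.  These posteriors are low-dimensional
  (<= 8 parameters), unimodal, with polynomial tails inherited from the t
  priors, so the t proposal dominates the target tails; chains are
  genuinely independent (4 chains x 1000 draws by default) and close to
  iid.  Exactness does not depend on the proposal being right — only
  efficiency does, and the R-hat/ESS gate reports when it is not.
* **`ensemble`** — emcee with differential-evolution moves, walkers
  initialised around the mode and treated as chains for diagnostics.  A
  gradient-free cross-check engine; slower to mix on the same budget.
* **`laplace`** — draws from N(mode, H^-1).  Deterministic and fast, used
  in unit tests and quick exploration; it is an approximation, not MCMC,
  and is labelled as such in fit metadata.

Numerical notes: the Bernoulli log-likelihood uses `y*eta -
log1p(exp(eta))` via `logaddexp` (stable for any eta); the Hessian is a
central difference of the analytic gradient; a non-positive-definite
Hessian falls back to a diagonal covariance (0.5^2) so the sampler still
runs and the diagnostics judge the result.

## Data preparation

* **Missingness** is strictly complete-case per analysis feature set; no
  imputation anywhere.  Different fitted models may therefore use slightly
  different n; each report row records its n.  Selection stages that
  compare models pointwise (the wrapper) complete-case once on the union
  of the involved features so every model scores the same rows and paired
  standard errors are well defined.
* **Z-scoring** uses the population-std convention (divisor n) so a
  standardized column has std exactly 1; the sample-std variant is a flag.
  The transform (mean, std per feature) is stored on the fit for mapping
  new raw data; it is computed once on the analysis table, not per fold —
  mirroring the workflow this pipeline reproduces.  A fold-safe variant is
  possible by re-running `zscore_normalize` inside folds, but is off by
  default.
* **Outliers** are only reported (quartiles and 1.5 IQR fences via
  `iqr_fences`); inclusion decisions belong to domain experts.

## Feature construction and selection

1. **Augmentation.**  Pairwise products of the three z-scored biomarkers,
   including self-products: six derived columns.  A product is positive
   when the two biomarkers are concordant, negative when discordant, which
   is the interpretable interaction the biomarker analysis targets.  The
   self-product inclusion is what makes three biomarkers yield six derived
   features; with plain cross-products it would be three.
2. **Ranking.**  Random-forest Gini importance (500 trees, fixed seed,
   scikit-learn) on the complete-case subset; exact ties keep input order.
   Ranking runs once per target, since the two clinical problems produce
   different candidate lists.
3. **Pruning.**  In rank order, drop any feature with |Pearson r| >= 0.5
   (pairwise-complete) against an already-retained feature.
4. **Exclusions.**  Config entries, defaulting to gender (label-leakage
   risk) and DLCO/VA (excessive missingness: 9 of 39).
5. **Grouping.**  Top-2 survivors of each clinical group — functional,
   BAL marker, biomarker (products inherit the biomarker group) — give six
   candidates per target.
6. **Screening.**  One Bayesian fit per single candidate and per unordered
   pair: 6 + 15 = 21 models.  A candidate is dropped when any model gives
   its coefficient probability > 0.10 of lying in [-0.05, +0.05], or when
   its sign is ambiguous across models (P(b>0) >= 0.6 somewhere and <= 0.4
   elsewhere).  The 0.10 drop threshold and the 0.6/0.4 ambiguity band are
   this package's operationalisation of "high probability near zero" and
   "incoherent sign"; both are config entries.
7. **Wrapper selection.**  Rank-nested subsets M1 c M2 c ... scored by
   ELPD-LOO; the subset with the highest score wins.  A free-form model
   list is accepted for hand-curated comparisons.

## ELPD-LOO

The expected log pointwise predictive density under leave-one-out:
contribution_i = log E_post[p(y_i | theta)] with the point held out, summed
over points; se = sqrt(n var(contributions)).  Two estimators:

* **Exact refit** (reference): n refits, no approximation.  At n = 39 this
  costs seconds per model and is the default for model selection.
* **PSIS** (fast path): importance ratios 1/p(y_i | theta_s) from the
  full-data posterior; the top 20% of ratios per point are replaced by
  expected order statistics of a generalized Pareto fitted to the tail
  exceedances (Zhang-Stephens profile estimator with small-tail
  regularisation), log-weights truncated at the raw maximum.  Per-point
  Pareto k > 0.7 is flagged as unreliable.  The smoother is implemented
  in-package and cross-checked in tests against ArviZ's `psislw` (the two
  agree to machine precision when ArviZ's tail rule selects the same 20%
  tail), and PSIS scores are validated against exact refits within two
  combined standard errors on small-cohort simulations.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, so
the pipeline is testable without patient data:

* **Marginals**: independent truncated normals matching each feature's
  published min/max/mean/std (e.g. Age in [46, 80], mean 66.46, std 7.56;
  KL-6 in [0, 56.87], mean 11.23, std 14.76), sampled by inverse-CDF on
  the truncated interval — exact, vectorised, no rejection loops.  An
  optional Gaussian copula accepts a correlation matrix for stress-testing
  the pruning stage.
* **Missingness**: exactly the published per-feature counts (23 cells
  total, 9 of them DLCO/VA), rows uniform without replacement, targets
  never masked.
* **Labels**: planted through the same logistic mechanism the classifier
  fits — p_i = logistic(b0 + b . z_i) — either Bernoulli draws or top-k
  thresholding when fixed class counts are required (19/20).  Default
  planted signs follow the reported coefficient directions: for diagnosis
  Lin% and miR-21 negative, miR-21 x miR-92a positive; for prognosis Age
  and DLCO negative, KL-6 positive.  Magnitudes (0.8-1.2 on the z scale)
  are set to the moderate-effect regime those posteriors describe.
* **Nominal covariates**: P(male) = 0.7, P(smoker) = 0.5 — the source
  setting reports male predominance and no smoker difference without
  counts; these are documented arbitrary defaults.
* **Prognosis split**: 19 RAPID / 20 SLOW, mirroring the balanced
  description; exact counts are not published.

What the generator does **not** emulate: real clinical correlation
structure (marginals are independent by default), possible log-normality
of the skewed biomarkers (the truncated normal reproduces the printed
moments but not the full shape), and longitudinal follow-up.  Passing
tests therefore demonstrate that the machinery is correct under the
assumed data-generating process, not that the clinical findings replicate.

## Evaluation

Every metric is a posterior distribution: per draw s, hard labels are
p_i^s > 0.5 (strictly greater — a probability exactly at the cutoff
predicts the negative class), giving one accuracy/sensitivity/specificity
value per draw, summarised by mean and std.  Metrics are computed
in-sample on the fitted table by default (an LOO-predictive variant can be
assembled from the LOO machinery).  Per-sample summaries carry an
"uncertain" flag when mean ± std crosses 0.5: no decision should be made
on such samples.  Coefficient reports give mean, std, 5/50/95% quantiles,
P(b in [-0.05, +0.05]) and P(b > 0) per parameter, with the intercept
included but flagged as outside the relevance assessment.

## Problem sizes and defaults used in checks

Automated checks run at deliberately modest sizes chosen to make the
statistical assertions stable: structural counts at the study size
(n = 39), estimator agreement on ten n = 39 cohorts, parameter recovery
on fifty planted fits at n = 400 with 2000 retained draws per fit, and
selection behaviour over ten seeds.  The sampler default for final
inference remains 4 x 1000 draws after 1000 warmup steps.

## Known limitations

* Independence MH would mix poorly if a posterior were multimodal or very
  far from its Laplace calibration; the R-hat/ESS gate detects this, and
  the `ensemble` engine is the fallback.
* In-sample expected metrics are optimistic relative to LOO-predictive
  metrics; they quantify posterior uncertainty, not generalisation.
* With near-separable small cohorts (fixed-count thresholded labels),
  coefficient posteriors are wide and PSIS k diagnostics frequently flag
  points; exact-refit LOO is the default for selection precisely because
  of this regime.
* The screening drop rule depends on two chosen thresholds (0.10 near-zero
  probability, 0.6/0.4 sign band); sensitivity to these is easy to probe
  via config but no automated sweep is provided.
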