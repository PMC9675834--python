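# Methods

`popmediate` estimates how much of a binary-group difference in a log-scale
outcome is mediated by a panel of correlated chemical exposures, in the
setting of a complex survey sample with left-censored exposure measurements.
The motivating application is the Black/White difference in log leukocyte
telomere length (LTL, log T/S ratio) and serum concentrations of 15
persistent organic pollutants (9 PCB congeners, 3 dioxins, 3 furans) in a
stratified, clustered, weighted national survey. This note records the
models, the numerical choices, and what the synthetic-data tests do and do
not establish.

## Mediation models

All single-mediator analysis follows the product-of-coefficients
decomposition. With outcome `Y` (log scale), group `A` (binary), adjustment
covariates `Z` (standardized age and age², sex, 5-level education, log
cotinine, log lipids, white-cell count, five differential percentages,
survey-cycle indicator), and mediator `M_j` (log concentration):

    Y   = mu_0 + mu_a A + Z' mu_z + e                 (total effect  mu_a)
    M_j = alpha_0j + alpha_aj A + Z' alpha_zj + e     (exposure model)
    Y   = beta_0j + beta_aj A + beta_mj M_j + Z' beta_zj + e   (outcome model)

The indirect effect (IE) through `M_j` is `alpha_aj * beta_mj`, the direct
effect is `beta_aj`, and on any one completed dataset

    mu_a = beta_aj + alpha_aj * beta_mj

holds *exactly* — an algebraic identity of nested weighted least-squares
fits sharing weights and covariates — which the test suite asserts at 1e-8.
Percent mediated is `100 * IE / mu_a`; values outside [0, 100] (inconsistent
mediation) are legal and flagged. IE inference uses the first-order Sobel
standard error `sqrt(alpha² Var(beta_m) + beta_m² Var(alpha))` (a
second-order option adds the Var×Var term) with a normal reference, and the
15 single-mediator p-values are Benjamini–Hochberg adjusted jointly.

The joint (mixture) model replaces `beta_mj M_j` with `M' beta_m` over all
15 chemicals and the exposure model with a multivariate regression; the
global IE is `alpha_a' beta_m` and `mu_a = beta_a + alpha_a' beta_m` again
exactly for the unpenalized fit. Because the chemicals are highly collinear
(pairwise r up to ~0.95), the unpenalized `beta_m` suffers severe variance
inflation; a ridge penalty on the mediator columns only (never on `A` or
`Z`, which would bias the direct effect) stabilises it. The penalty is
selected by k-fold cross-validation on weighted prediction error, and
inference for both joint estimators uses a nonparametric participant
bootstrap with percentile intervals and the `+1`-corrected sign-flip
p-value. By default the penalty is re-selected inside every bootstrap
replicate (honest inference); a fast mode freezes it. An optional cluster
mode resamples whole PSUs within strata instead of individual participants
(off by default, matching the estimators' design-agnostic inference).

Summary-score mediators collapse the panel into `S = sum_j w_j M_j` and run
`S` through the single-mediator machinery (the fully design-aware route):

* **PCA** — first principal component of the standardized log
  concentrations (correlation-scale PCA, computed once on the stacked
  completed data), sign-oriented to a positive weight sum;
* **PDM** (principal direction of mediation) — the unit-norm `w` maximizing
  `|alpha_w * beta_w|`, the mediated effect of the score. Internally the
  objective reduces to `f(w) = (w'a)(w'b)/(w'Cw)` with `a` the per-chemical
  group coefficients and `b`, `C` weighted residualized cross-products
  (Frisch–Waugh), so each evaluation is a few matrix products; it is
  maximized by seeded multi-start BFGS on the (scale-invariant) squared
  objective, 20 restarts including `a`- and `b`-aligned starts. Tests verify
  the optimum against a closed-form two-dimensional reduction;
* **TEQ** — a priori toxic-equivalency-factor weights applied to
  natural-scale concentrations (chemicals without a TEF drop out), with the
  score log-transformed before modelling; non-positive scores are offset by
  half the smallest positive score with a warning. Two TEF tables ship: the
  table used in the original score construction (default; PCB 118 = 0.030)
  and the WHO 2005 consensus values (PCB 118 = 0.00003). Score mediation is
  invariant to positive rescaling of `w`, so the sum-vs-average distinction
  is immaterial for inference.

Subclass sensitivity repeats the PCA route within chemical subclasses (all
PCBs; non-ortho PCBs; non-dioxin-like PCBs; dioxins; furans).

## Survey estimation

Every design-aware model is fit by weighted least squares with the
linearization (Taylor) covariance for stratified cluster samples: the
between-PSU covariance of weighted score totals within strata, scaled by
`n_h/(n_h − 1)`, sandwiched in `(X'WX)^{-1}` — the with-replacement
first-stage approximation of standard survey software. It is invariant to
weight rescaling and agrees with a delete-one-PSU jackknife within 15% on
30×2 designs (tested). Wald tests use a normal reference by default; a t
reference with PSUs − strata degrees of freedom is available and is what the
coverage simulation uses (with ~10–15 design df the normal reference covers
~90–93%, the t reference ~95%). Strata with a single PSU are a hard error.
The joint OLS/ridge estimators use the weights in point estimation but not
strata/PSUs in inference — collapsing a multivariate-response survey fit is
out of scope, which is exactly why the summary-score route exists.

## Censored imputation

Concentrations below the limit of detection (LOD) are left-censored. Each
chemical is modelled on the log scale with a censored-normal (Tobit)
likelihood — density contributions for detected values, `Phi((log LOD −
x'beta)/sigma)` for non-detects — maximized by L-BFGS-B with analytic
gradients over `(beta, log sigma)`. Predictors are standardized internally
(the raw covariate scales condition the surface badly; standardization cuts
the iteration count by roughly an order of magnitude) and coefficients are
mapped back. Chemicals with more than 50% non-detects in any survey cycle
are excluded up front (strictly-greater rule: exactly 50% is retained).

Imputation proceeds per survey cycle (batch), sequentially from the least to
the most censored chemical (ordered by the reference cycle), each model
conditioning on log outcome, group, education, age, sex, log cotinine,
blood-composition variables, log lipids, and the other chemicals' current
completed values. Non-detects are drawn from the fitted normal truncated
above at log(LOD). Numerical choices:

* Each of the `m` chains fixes one uniform variate per censored cell and
  maps it through the current truncated-normal fit (inverse-CDF coupling),
  making the sweep a deterministic fixed-point iteration.
* Even so, with 15 mutually censored, strongly correlated chemicals the
  coupled refits keep perturbing one another at the ~1e-2 scale, so the
  default schedule is a fixed two full passes with early stop when
  imputed-cell means move less than 1e-3; `strict=True` turns residual
  non-convergence into an error with per-chemical diagnostics. At the
  default censoring levels two passes recover pooled means within ~0.01 and
  pairwise correlations within ~0.03 of the uncensored truth (n = 5000).
* Draws are taken at the MLE without a posterior draw of `(beta, sigma)` —
  improper multiple imputation. The between-imputation variance is slightly
  understated; at the 13–37% censoring levels of the application the effect
  on pooled mediation SEs is small.
* Imputation models are unweighted (whether the original analysis weighted
  them is unstated); the mediation fits that consume the completed data are
  fully weighted.
* A calibration diagnostic replaces the original "visual" quality check:
  for every imputed cell the fitted truncated normal implies a conditional
  quantile; a chemical/cycle whose mean conditional quantile leaves
  [0.35, 0.65] is flagged as systematically too low/high (the failure mode
  that led to excluding two chemicals in the original analysis).

Downstream estimates are combined across the `m` completed datasets by
Rubin's rules (Barnard–Rubin small-sample df when a complete-data df is
supplied). Point summaries (direct effect, percent mediated) use means of
the per-imputation points. For the bootstrap-based joint estimators the
replicate distributions are bootstrapped within each completed dataset and
mixed before taking percentile intervals (boot-then-pool).

## E-value

The mediation E-value converts the (continuous-outcome) IE to an approximate
risk ratio via the standardized difference, `RR = exp(0.91 * beta/sd_Y)`
with `sd_Y` the analytic-sample sd of log LTL, then evaluates
`E = RR + sqrt(RR(RR−1))` (RR < 1 inverted first). The CI E-value uses the
interval bound closer to the null and is 1 when the interval crosses it.
`E = 1.35` corresponds to `RR = E²/(2E−1) ≈ 1.07` — a modest confounder
association suffices to explain away an IE of this size.

## Synthetic cohort

The generator emulates the analytic sample, not the full survey machinery:

* `n = 1251` participants by default, 25.7% in group `A = 1`; covariates
  drawn to match the published marginal summaries (age 50.8 ± 19.3,
  education shares, log cotinine −0.55 ± 3.80, log lipids 6.48 ± 0.22,
  white-cell count and differentials; the differential slack keeps the five
  percentages summing to 100 ± 2 without exact collinearity).
* 15 jointly log-normal chemicals with a block correlation structure
  (within-PCB 0.63–0.95, within-dioxin/furan 0.48–0.75, cross-block 0.45,
  log sd 0.6) matching the published correlation ranges; group shifts
  `alpha_a` patterned on the observed race differences (largest for PCBs
  187, 138, 153, 118, 126).
* Outcome coefficients `beta_m` positive for every PCB and small (0.001)
  for dioxins/furans — the published qualitative pattern — scaled so the
  global IE `alpha_a' beta_m ≈ 0.019`, the direct effect 0.035, and the
  total 0.054, the published magnitudes; residual sd 0.23 on log LTL.
* LODs are set per chemical per cycle as empirical quantiles at the
  published percent-below-LOD targets (13.3–36.9%), so realized censoring
  matches the targets by construction and converges to them as `n` grows.
* Design: 15 strata × 2 PSUs by default, balanced assignment independent of
  the outcome, log-normal weights (sd 0.4 on the log scale) scaled to a
  nominal population; an `informative_design` knob ties weights to age for
  non-ignorable-design experiments.
* Covariates are independent of exposures by default (`confounding_strength
  = 0`), so the mediation identification assumptions hold by construction
  and estimators can be tested for exact parameter recovery.

Ground truth: the generator reports the global IE `alpha_a' beta_m`, the
per-path products, and — because the single-mediator outcome model's
`beta_mj` absorbs effects transmitted by omitted correlated chemicals — the
probability limit of each *single-mediator* estimand,
`alpha_aj (Sigma_m beta_m)_j / (Sigma_m)_jj`, which is the right target for
recovery tests of the one-at-a-time models. Total = direct + global IE holds
exactly by linearity.

What passing tests do **not** show about real data: the generator has no
exposure–covariate confounding, no exposure measurement error, no
missingness outside censoring, linear effects only, and an ignorable design
by default — so the simulation validates the estimators under their stated
assumptions, not the causal interpretation of any real-data analysis.

## Problem sizes used in validation

Chosen once as a balance of Monte-Carlo error against a desk-scale runtime:
recovery, 50 replicates at n = 5000 with m = 3 imputations (per-mediator
pooled-IE bias < 0.005) plus a dedicated 600-replicate complete-data arm for
the CV-ridge global-IE shrinkage bias (within 20% of truth; censoring adds
no measurable further attenuation, and the cheap replicates keep the
Monte-Carlo error of the bias estimate at ~0.7%); Sobel size, 500 replicates
at n = 1000 (conservative under the product null); bootstrap coverage, 100
replicates × B = 200 at n = 1000; variance inflation, 50 cohorts at n = 500,
pairwise r = 0.95, with the ridge penalty CV-selected per cohort and frozen
across that cohort's bootstrap (fast mode); oracle checks at n = 1500 with a
30 × 2 design. CI coverage for the survey total effect uses the t reference
with design df.

## Known limitations

* Improper MI (no parameter draws) slightly understates between-imputation
  variance.
* The CV-ridge global IE is shrinkage-biased toward zero by construction:
  measured at −19.7% ± 0.7% under the default conditions (600 cohorts) —
  statistically indistinguishable from the 20% working bound the validation
  uses. It buys a large variance reduction under collinearity; treat the
  ridge point estimate as conservative.
* PDM overfits in small samples (it maximizes the in-sample mediated
  effect); its published near-zero result is reproduced qualitatively only
  in the sense that the optimizer is faithful, not that the direction
  generalizes.
* No replicate-weight (BRR/Fay) variance mode; the jackknife exists only as
  a validation oracle in the test suite.
* The joint OLS/ridge estimators do not account for strata/PSUs in
  inference (weights enter point estimation only).
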