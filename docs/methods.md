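# Methods

## Model

The analysis object is a recursive observed-variable path model over a
subject-level OHCA registry. Endogenous nodes are the binarized low-SEP
exposure, the mediators in temporal order (witnessed status, bystander CPR,
initial shockable rhythm, ED level 1–2; plus CAG and TTM in the
admitted-only model) and survival to discharge. Confounders (age in years,
male sex, diabetes, hypertension, metropolitan residence) are exogenous with
freely correlated covariance and, by default, an edge into every endogenous
node.

All endogenous variables are binary and modeled on the **linear-probability
scale**. This is the central modeling convention: pathway effects and the
total effect are then risk differences (e.g. a total effect of −0.03 means a
3-percentage-point lower survival probability for the low-SEP group), and
products of coefficients along a path are themselves risk-difference-scale
quantities, which is what makes the product-of-coefficients decomposition
and the mediation proportions well defined. The cost is that a linear
probability model can, in principle, imply probabilities outside [0, 1];
the synthetic generator counts and clips such events (the shipped defaults
never clip).

### Estimation

Writing `y = B y + G x + zeta` with diagonal `Cov(zeta) = Psi` and free
`Cov(x) = Phi`, the implied covariance of `(x, y)` is assembled from the
reduced form `A = (I−B)^{-1}`. The fit minimizes the ML discrepancy
`F = ln|Sigma| + tr(S Sigma^{-1}) − ln|S| − p`. Because the model is
recursive with diagonal `Psi`, the Gaussian likelihood factorizes along the
DAG and the exact minimizer is per-equation OLS computed from `S`; the
implementation starts there and runs an L-BFGS polish with the analytic
gradient `dF = tr[(Sigma^{-1} − Sigma^{-1} S Sigma^{-1}) dSigma]` until the
gradient norm is below 1e-6, flagging non-convergence rather than returning
silently. Conventions that differ across SEM software are fixed as: `S`
uses the N−1 divisor; `T = (N−1)·F`; degrees of freedom are
`p(p+1)/2 −` (number of free parameters, counting `Phi`'s `q(q+1)/2`).

"Robust ML" is implemented as ML point estimates plus (a) sandwich
parameter covariance built from per-observation estimating-equation scores
(bread: expected per-equation information, block-diagonal; meat: empirical
covariance of the stacked scores), and (b) a Satorra–Bentler-type mean
scaling factor `c = tr(U·Gamma)/df`, with `Gamma` the empirical
fourth-moment covariance of `vech` of the centered cross-products and `U`
the normal-theory residual weight `W − WΔ(Δ'WΔ)^{-1}Δ'W`,
`W = ½D'(Sigma^{-1}⊗Sigma^{-1})D`. With binary (platykurtic) indicators `c`
typically falls below 1. Fit indices can be computed from the plain or the
`c`-scaled statistic; both coincide when `c = 1`.

### Fit indices

RMSEA `= sqrt(max(T−df,0)/(df·(N−1)))`; SRMR uses correlation-metric
standardized residuals averaged over the lower triangle including the
diagonal; GFI `= 1 − tr((Sigma^{-1}S−I)²)/tr((Sigma^{-1}S)²)`; CFI
`= 1 − max(T−df,0)/max(T_b−df_b, T−df, 0)` against the independence
baseline (variances free, all covariances zero). A saturated model (df = 0)
is reported as RMSEA 0 and CFI 1 by convention.

### Pathways, proportions and intervals

Pathway sets are enumerated as simple directed paths (lexicographic order,
cross-checked against brute-force DFS). The "through M" effect sums the
products of edge coefficients over all paths containing M; "through M but
not through its intermediate confounders" additionally excludes paths that
visit any exposure-affected variable influencing both M and the outcome.
In a recursive DAG these variables are exactly M's mediator parents, so the
exclusion set is derived automatically from the graph (e.g. witnessed and
bystander CPR for initial rhythm; initial rhythm and ED level for CAG; ED
level for TTM). The decomposition identity
`total = direct + Σ (all simple indirect path products)` is asserted to
1e-10 at every call; through-mediator sets overlap, so their proportions
are *not* expected to sum to 100%.

Standard errors use the multivariate delta method (pathway effects are
multilinear in the free coefficients, so gradients are closed-form) against
the robust parameter covariance; the mediation proportion `100·theta/tau`
gets a delta interval for the ratio. A percentile bootstrap (resampling
subjects, refitting the closed-form ML per resample) is provided as an
alternative; the proportion is undefined at `tau = 0` and, in the shipped
decomposition table, proportions are suppressed when the underlying
effect's 95% CI covers zero. Mediation proportions are reported to 1
decimal and effects to 3 decimals in CSV outputs.

## Synthetic registry generator

The generator is the package's stand-in for the restricted insurance-linked
registry and defines the study conditions for every test:

* **Cohort structure.** Five SEP groups with the published sizes (40 483 /
  26 955 / 21 625 / 22 201 / 10 252; total 121 516). Group-specific
  confounder distributions are calibrated to the published descriptive
  table: age as a truncated normal (bounds 19–100 y) with the group median
  as mean and IQR/1.349 as SD — the exact family is this package's choice,
  the source reports only medians and IQRs — and sex/diabetes/
  hypertension/metropolitan as per-group Bernoulli draws at the printed
  prevalences.
* **Structural equations.** Linear-probability by default (a logistic link
  is available per node for realism, at the price of losing exact linear
  estimands). Age enters centered at 70 years; slopes are per year.
  Response time is generated directly as the binary <8-min indicator;
  continuous response times are out of scope.
* **Calibration.** All SEP effects flow through the Medical-Aid indicator;
  coefficients were chosen once so the MA-vs-NHI total effect on survival is
  ≈ −0.03 with mediation proportions near 15% (witnessed), 5% (bystander
  CPR), 40% (initial rhythm) and 9% (ED level), and mediator marginals near
  the printed cohort values. Two deliberate departures from the real cohort:
  (1) baseline survival is ≈ 13% rather than 7%, because keeping every
  subject's linear-probability survival risk non-negative with a
  shockable-rhythm risk difference of 0.26 requires a higher intercept;
  (2) NHI Q2–Q4 carry no SEP effects of their own (no per-group intercept
  offsets), because offsets correlated with the group-specific confounder
  distributions would make the MA-vs-rest analysis model misspecified and
  destroy exact parameter recovery. A `group_offsets` hook exists for users
  who want the extra realism.
* **Outcome plumbing, full-population config.** Survival to discharge is
  generated directly from its full-population equation; admission is a
  superset (discharge forces admission, non-survivors are admitted with an
  extra probability), and CAG/TTM are generated only among the admitted,
  with zero value elsewhere. This keeps the all-patients path model exactly
  correctly specified.
* **Admitted-only config.** Admission is generated from confounders alone,
  making selection independent of exposure and mediators given the
  confounders, so restricting to admitted subjects leaves all structural
  truths intact; CAG, TTM and discharge are then generated among the
  admitted with nonzero treatment edges (CAG→survival 0.30, TTM→survival
  0.15). Under linear-probability bounds and a realistic ~5-pp MA-vs-NHI
  gap in shockable rhythm, the admitted-only rhythm mediation proportion
  calibrates to ≈ 30%, with CAG ≈ 19% and TTM ≈ 4%; pushing rhythm much
  higher would require an implausible ~0.9 risk difference of rhythm on
  survival, so the admitted conditions favor plausibility over matching any
  particular published decomposition.
* **Missingness.** Only the six Utstein mediators can be masked, at the
  registry's reported proportions (location 2.9%, witnessed 9.0%, bystander
  CPR 2.5%, bystander AED 1.4%, response time 0.2%, initial rhythm 0.6%),
  with a logistic missing-at-random mechanism in fully observed covariates
  whose intercept is solved numerically to hit the target rate; exposure
  and outcomes are never masked.
* **Determinism.** One master seed; per-node child streams are spawned from
  a `SeedSequence`, so adding a node never reshuffles unrelated draws, and
  identical configs produce byte-identical CSVs.

What the generator does **not** emulate: exposure–mediator or
mediator–mediator interactions, continuous response-time dynamics, calendar
time, EMS-system geography, or outcome-dependent missingness. Passing tests
therefore demonstrate correctness of the estimators under a
correctly specified linear causal structure with MAR missingness — not
robustness to the interaction effects, non-linearities or informative
missingness a real registry may harbor.

## Imputation

Single stochastic regression imputation, matching the workflow the package
reproduces: one logistic model per missing-prone column, fitted on complete
cases by the package's own IRLS engine, predictors being the confounders,
the binarized exposure and the temporally upstream mediators (a
reconstruction — the source's exact predictor lists are not public).
Columns are completed in temporal order, each cell drawn
Bernoulli(predicted probability) rather than thresholded, preserving
binomial variability (a dedicated test distinguishes this from
deterministic regression imputation). Multiple-imputation pooling is
deliberately out of scope; repeated single imputations with different seeds
are available for sensitivity checks.

## Mediator screening and odds-ratio tables

The Baron–Kenny screen runs two multivariable logistic regressions per
candidate — exposure→mediator and mediator→outcome given exposure and
confounders — and flags a mediator when both are significant two-sided at
α = 0.05. The classic step-4 attenuation of the exposure coefficient is
reported descriptively but not tested, and is not required for the flag
(a deliberate default, since the reference workflow's exact rule is not
documented). Logistic regression is Newton/IRLS with step-halving (the
line-search tolerance is relative to |log-likelihood| so large-n fits
cannot stall on float noise), score-norm convergence below 1e-8, covariance
from the inverse observed information, and explicit errors on rank
deficiency, separation and non-convergence. Age enters adjustment models
continuously by default; a ≥65 categorical option exists. The OR table
indicator-codes the 5-level SEP exposure against NHI Q1 with Wald 95%
intervals; crude tables are the same call with an empty confounder list.

## Numerical choices and degenerate inputs

* Sample covariance must be positive definite; violations raise.
* `Psi` entries are kept positive during optimization by rejecting
  non-positive proposals (infinite discrepancy).
* Intervals use the normal 97.5% quantile; two-sided p-values are Wald.
* Bootstrap refits use the closed-form ML solution (no polish) for speed —
  legitimate because the closed form *is* the exact minimizer — and error
  if more than 5% of resamples fail.
* Tie-breaking in path enumeration is lexicographic by node sequence.
* An empty pathway selection returns effect 0 with SE 0.

## Problem sizes

Tests and the acceptance script run the generator at the published cohort
size (121 516) or below; the parameter-recovery study uses 100 replicates
of 200 000 subjects, and interval-calibration studies 100 replicates of
20 000 with 300-replicate bootstraps. These sizes were chosen to keep
Monte-Carlo error well below the effect sizes under study.

## Known limitations

* Binary outcomes on the linear-probability scale can clip; the generator
  exposes a clip counter, but the fitted model has no safeguard beyond it.
* The robust scaling factor assumes i.i.d. subjects — no clustering by
  region or hospital.
* "Robust ML" here is one concrete choice (sandwich + mean scaling); other
  software's robust estimators (e.g. mean-and-variance adjusted statistics,
  WLSMV) will differ in finite samples.
* Residual covariances among mediators are fixed at zero (diagonal `Psi`);
  latent variables and FIML for missing data are out of scope.
* The mediation estimands are linear path-model quantities; they are not
  counterfactual natural direct/indirect effects and do not accommodate
  exposure–mediator interaction.
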