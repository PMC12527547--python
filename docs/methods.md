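# Methods

`hiermice` implements one-stage multilevel multiple imputation (MLMI) for
individual-participant-data (IPD) meta-analyses in which covariates are
*systematically* missing (a study never measured the variable) and
*sporadically* missing (a study measured it but some participants lack it)
at the same time.  This note records the model, the algorithms, the
numerical choices and the limitations of the package; nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Analysis model

The substantive model is a two-level generalized linear mixed model
(GLMM): for participant *j* in study *i*,

    g(E[y_ij]) = x_ij' β + w_ij' u_i ,   u_i ~ N(0, T)

with identity link for a continuous outcome and logit link for a binary
one.  The default analysis model used throughout the simulation harness is
`y ~ x1 + x2` with a random intercept and a random slope on the binary
covariate x1, so T is 2×2 with diagonal (τ0², τ1²).  Fixed effects carry
standard errors; the random-effects variances are reported as point
estimates only.

## Imputation model and posterior draws

Each incomplete variable Z is imputed from its own GLMM given all other
variables (fully conditional specification): binomial-logit for binary
targets, Poisson-log for counts, Gaussian for continuous ones, with a
random intercept and, by default, a random slope on the analysis outcome.
One imputation requires a draw of (β*, Ω*, {b*_i}):

1. **Fit** the imputation GLMM on rows with observed target and predictors.
2. **β\*** ~ N(β̂, V̂), where V̂ is the observed-information covariance of
   the fixed effects conditional on the estimated Ω (Schur complement of
   the joint (β, b) Hessian at the conditional modes — what `glmer`'s
   `vcov` reports).
3. **Ω\*** ~ Inverse-Wishart(m, S) with S = Σ_i b̂_i b̂_i' + 10⁻⁸·I over the
   m studies that observe the variable at least partially; systematically
   missing studies do not contribute.  The convention is pinned by a test
   of the mean identity E[Ω*] = S/(m − q − 1).  The draw requires
   m ≥ q + 2; when fewer studies observe the target, the imputer falls
   back to a random-intercept-only model (q = 1).
4. **b\*_i**:
   - *systematically missing studies*: b*_i ~ N(0, Ω*) — the prior.
   - *studies observing the variable*: an accept–reject draw from the
     exact conditional posterior p(b | Z_i,obs, β*, Ω*) ∝ f(Z_i,obs | b, β*)
     · φ(b; 0, Ω*).  The proposal is the prior N(0, Ω*); the bound is the
     cluster likelihood maximized over b at the drawn β* (the ratio being
     bounded is a function of b at fixed β*, so the bound must use β*,
     not β̂).  A proposal b′ is accepted iff log U ≤ ℓ(b′) − ℓ_max, with
     every comparison in the log domain.
5. **Impute** each missing cell by sampling the family distribution at
   η = x'β* + w'b*_i, with η clipped to ±20 before exponentiation so a
   pathological Ω* tail cannot produce astronomical Poisson draws.

For continuous targets the conditional posterior of b_i is itself normal,
so `impute_normal_hier` draws it in closed form and draws the residual
variance as σ̂²·df/χ²_df; a test checks that the closed form and the
accept–reject sampler produce the same distribution on a Gaussian cluster.

**Accept–reject exhaustion.**  Acceptance rates fall when a cluster is
very informative relative to the prior proposal.  After `max_tries`
(default 10 000) proposals the sampler returns a draw from the Laplace
approximation N(b_mode, (−∇²ℓ(b_mode) + Ω*⁻¹)⁻¹) of the same posterior and
logs the study; in exactly those clusters the Laplace approximation is
excellent.  Proposals are evaluated in vectorized batches, so typical
draws cost microseconds.

## GLMM fitting

The fitter maximizes the Laplace-approximate marginal likelihood by
alternating

- a penalized-IRLS joint Newton solve for (β, b_1..b_m) at fixed Ω,
  using block elimination of the per-study blocks (all per-cluster
  algebra is batched; no Python loop over studies), and
- the EM update Ω ← (1/m) Σ_i (b̂_i b̂_i' + V_i), where V_i is the
  conditional covariance of b_i (plus the analogous residual-variance
  update for the Gaussian family, for which the scheme is the exact ML EM
  algorithm).

Because EM contracts slowly near variance boundaries, the fixed-point map
is accelerated by SQUAREM-style squared extrapolation, run in Cholesky
coordinates of Ω (log coordinates for σ²) so extrapolated iterates stay in
the positive-definite cone.  Convergence is declared when the relative
change of the map output falls below `tol` (default 10⁻⁵ for analysis
fits; the within-cycle imputation refits use 10⁻³, since the chained-
equations loop refits every cycle and parameter draws dominate that
precision).  Non-convergent fits are retried with a random intercept only
and flagged.  A held-out check pins the Gaussian path to statsmodels'
`MixedLM` (ML) within 10⁻³ on a fixed dataset; the binomial path was
verified against `lme4::glmer` during development.

`V̂` is conditional on Ω̂ (no propagation of Ω uncertainty into β*): this
is the non-iterative simplification that makes one draw per imputation
possible without a Gibbs sampler, and it slightly understates the
β-posterior spread when the number of studies is small.

## Comparator methods

- **STI** (stratified imputation): single-level imputation model with
  fixed study-indicator dummies (one-hot, no global intercept).  Binary
  targets use Bayesian logistic imputation (coefficients drawn from the
  asymptotic normal posterior); count targets use type-1 predictive mean
  matching with k = 5 donors matched on the predicted mean (donors scored
  at β̂, recipients at β*).  For studies where the target is
  systematically missing, the study-intercept coefficient is the
  arithmetic mean of the observed studies' intercepts.  Perfect separation
  of a dummy triggers a ridge-stabilized refit (λ = 10⁻⁴) with a warning.
- **2STG** (two-stage): per-study GLM fits (stage 1; studies with < 10
  observed rows or separated fits are dropped, at least 3 must survive)
  combined by a method-of-moments multivariate random-effects
  meta-analysis (between-study covariance = PSD-truncated moment
  estimator; GLS pooling).  Imputation coefficients are drawn per study
  from the shrinkage conditional posterior (observed studies) or the
  predictive distribution around the pooled draw (systematic studies);
  all of a study's missing cells — sporadic or systematic — are imputed
  from that drawn study model, which is the "treat sporadic as
  systematic" adaptation at the draw level.  MoM rather than REML keeps
  the comparator deterministic and dependency-light; its qualitative
  behaviour, not numerical identity to any published implementation, is
  the test surface.
- **CCA**: listwise deletion of rows missing any analysis variable;
  studies losing all rows drop out.

## Chained equations

Defaults follow the benchmark design: m = 5 imputations, 10 cycles,
visit order "monotone-auto" (ascending missing fraction), predictors of
each conditional model = all other variables including the outcome.  The
initial fill samples uniformly from the variable's observed values within
the same study, or from the pooled observed values where a study observes
none (the source design does not state an initial-fill rule; this one is
declared, not inferred).  Chains are independent sub-streams spawned from
one seed: identical seeds give bit-identical stacks.  Observed cells are
never modified.  Rubin's rules pool the m analysis fits (classical
large-sample degrees of freedom, no small-sample correction — left as an
extension); random-effects variances are pooled by their arithmetic mean,
with no interval, since the pooling rule defines none for them.

## Synthetic-data generator

The generator emulates a CKD-style IPD-MA (binary alcohol-use covariate
x1, comorbidity count x2, smoking-status outcome y):

    x1_ij ~ Bern(expit(α0 + a_i1)),  x2_ij ~ Pois(exp(γ0 + γ1 x1 + a_i2)),
    (a_i1, a_i2) ~ N(0, Ψ);  y from the analysis GLMM with (u_i0, u_i1) ~ N(0, T).

Defaults: β = (−0.5, 0.4, 0.2), σ² = 1, α0 = −0.3, (γ0, γ1) = (0.8, 0.2);
heterogeneity levels set τ0² = τ1² = 0.05 / 0.2 / 0.5 (weak / moderate /
strong) with correlation 0.3, and Ψ scaled identically.  These magnitudes
are chosen as plausible for the motivating epidemiological setting and are
fully configurable; every recovery check is truth-relative, so conclusions
do not hinge on the particular values.  The random slope of the outcome
model multiplies x1 (the binary covariate).  The benchmark grid fixes
3 000 participants split equally across {6, 10, 15, 20, 30} studies,
systematic-missingness proportions {0.10, 0.25}, and MCAR/MAR sporadic
missingness at a 10% target rate — 120 factorial cells.  Under MAR the
missingness of each covariate follows expit(ψ0 + ψ·y) with ψ = 0.5
(continuous y) or 1.0 (binary y) and ψ0 calibrated by monotone bisection
on the realized outcome sample to hit the target rate (closed form
logit(rate) when ψ = 0).  Systematic patterns are redrawn (≤ 100 times)
until every variable stays observed in ≥ 2 studies.

What the generator does **not** emulate: unequal study sizes, auxiliary
variables, MNAR mechanisms, effect-modifier structure, non-canonical
links, and real-data quirks such as rounding or truncation.  Passing
recovery tests therefore demonstrates internal validity of the method
under its own assumptions, not performance on any particular real IPD-MA.

## Problem sizes of the shipped checks

The heavier end-to-end checks run the benchmark cell "binary outcome, 10
studies × 300, π = 0.10 systematic, 10% sporadic MCAR, m = 5, 10 cycles"
with 100 replicates for the recovery block (both in the test suite and in
`scripts/acceptance.py`) and 40–50 paired replicates for the
method-ordering block — sizes chosen so the whole pipeline, including
roughly 10⁴ GLMM fits, completes comfortably on one CPU while keeping
Monte-Carlo error a few times smaller than the bands being checked (at
100 replicates the standard error of the β1 bias is about 0.01 against a
±0.1 band; coverage estimates carry a ±0.02 binomial SE).  The sampler diagnostics use 20 000
accept–reject draws against a 2 001-point grid posterior and 50 000
inverse-Wishart draws against the mean identity.

## Numerical choices and degenerate inputs

- Penalized-Newton line search halves the step until the objective is
  non-decreasing; per-cluster likelihood maximization is capped at
  ‖b‖∞ ≤ 20 (far beyond plausible logit/log effects) and flags probable
  separation.
- Covariance draws eigen-clip at 10⁻¹⁰ before Cholesky; the Ω* scale adds
  a 10⁻⁸ ridge against collinear conditional modes.
- Fewer than 2 studies observing a response is an estimation error;
  2 observing studies fit with q = 1 only.
- Empty clusters contribute log-likelihood 0 and b_max = 0.
- MAR calibration bisects on [−50, 50] to 10⁻⁶ and errors if the target
  rate is unreachable on the realized outcome sample.

## Known limitations

- Nominal/ordinal (multinomial) targets, gamma and inverse-Gaussian
  families are not implemented.
- Exactly two levels (participant within study); no crossed or three-level
  structures, and a single record per participant.
- The conditional models of the chained-equations loop are not guaranteed
  compatible with a joint multilevel model — the usual FCS caveat.
- τ estimates from the Laplace/ML fit are shrunken relative to REML,
  visibly so with few studies; comparisons across methods are therefore
  made against a same-fitter reference arm rather than against the
  generating value alone.
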