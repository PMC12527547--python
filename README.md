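# hiermice

Multilevel multiple imputation for clustered data — binary and count
variables that are **systematically** missing (never measured in some
studies) and **sporadically** missing (partially measured) at the same
time.

## Who this is for

Analysts running individual-participant-data (IPD) meta-analyses, or any
two-level study (participants within sites), who need to impute
categorical covariates before fitting a mixed-effects analysis model.
Deleting incomplete studies or participants wastes data and can bias
estimates; single-level imputation with study dummies distorts
between-study heterogeneity.  `hiermice` imputes each incomplete variable
from a generalized linear mixed model so the imputations respect the
clustering.

## The method

For an incomplete variable Z, the imputation model is a GLMM
`g(E[Z_ij]) = x_ij'β + w_ij'b_i`, `b_i ~ N(0, Ω)` (logit link for binary,
log link for counts), with a random intercept and a random slope on the
analysis outcome.  One imputation draws

- `β* ~ N(β̂, V̂)` from the fitted model,
- `Ω* ~ Inverse-Wishart(m, Σ b̂_i b̂_i')` over the m studies observing Z,
- per-study random effects `b*_i`:
  - studies that never measured Z: `b*_i ~ N(0, Ω*)` (the prior);
  - studies with partial data: an **accept–reject** draw from the exact
    conditional posterior `p(b | Z_obs, β*, Ω*)`, proposing from the
    prior and accepting `b'` iff `log U ≤ ℓ(b') − max_b ℓ(b)` — no Gibbs
    sampling, one draw per imputation,

then samples each missing cell from the family distribution at
`x'β* + w'b*_i`.  Chained equations (MICE) cycle this over all incomplete
variables; m completed datasets are analysed with the mixed model
`y ~ x1 + x2 + (1 + x1 | study)` and pooled by Rubin's rules
(`T = W + (1 + 1/m)B`).  Stratified imputation (STI), two-stage
imputation (2STG) and complete-case analysis (CCA) are included as
benchmark comparators, plus a synthetic-data generator with known truth.

See `docs/methods.md` for the full model, algorithms and limitations.

## Worked example

```python
from hiermice import MultilevelMICE
from hiermice.synthetic import SimConfig, make_incomplete

cfg = SimConfig(outcome_type="binary", n_studies=10, heterogeneity="moderate",
                pi_systematic=0.10, mechanism="MAR", mar_slopes=(1.0, 1.0),
                seed=42)
complete, incomplete, truth = make_incomplete(cfg)

model = MultilevelMICE(incomplete)        # methods inferred: mlmi for x1, x2
results = model.fit(m=5, cycles=10, seed=7)
print(results.pool().summary())
```

Output:

```
Multilevel Multiple Imputation — pooled analysis (Rubin's rules)
m = 5 imputations

parameter   estimate   std err    [0.025    0.975]        df
beta0        -0.5865    0.1722   -0.9241   -0.2489   7,745.4
beta1         0.2850    0.1325    0.0130    0.5570      26.8
beta2         0.2134    0.0302    0.1537    0.2731     128.1

random-effects parameters (arithmetic mean over imputations)
tau0_sq       0.2359
tau1_sq       0.0423
```

About 19% of each covariate was missing (one study lost each variable
entirely, the rest sporadically under MAR).  The pooled slopes `beta1`,
`beta2` estimate the generating values (0.4, 0.2) — `beta1` carries wide
uncertainty because only 10 studies inform a heterogeneous slope
(`tau1_sq`); its Rubin degrees of freedom (26.8) reflect substantial
between-imputation variance, i.e. genuine missing-data uncertainty, while
`beta2`'s tighter interval reflects the well-observed count covariate.

The same pipeline is scriptable from the shell:

```bash
hiermice simulate --config cfg.yaml --out sim/
hiermice impute sim/dataset.csv --method mlmi --m 5 --cycles 10 --out imp/
hiermice pool imp/
hiermice study --config cfg.yaml --replicates 100 --out metrics.csv
```

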