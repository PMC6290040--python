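# ordsem

A Monte Carlo laboratory for comparing three ways of estimating structural
equation models when the observed variables are ordinal (Likert-type)
indicators:

* **GSCA-ALS** — generalized structured component analysis: latent variables
  are exact weighted composites γ = Wz, and the global least-squares
  criterion φ = Σᵢ‖Vzᵢ − AWzᵢ‖² (V = [I; W], A = [C; B]) is minimized by
  alternating least squares under unit-variance component constraints.
* **CSA-ML** — covariance structure analysis by normal-theory maximum
  likelihood on the Pearson covariance S of the ordinal codes, minimizing
  F_ML = ln|Σ(θ)| + tr(SΣ⁻¹(θ)) − ln|S| − r.
* **CSA-DWLS** — the point-estimation core of WLSMV: thresholds from
  univariate margins, polychoric correlations from bivariate margins
  (Olsson's two-step method), then F_DWLS = (s − σ(θ))′ Ω_D⁻¹ (s − σ(θ))
  with diagonal asymptotic-variance weights.

The package ships the five-factor population model used for the comparison
(two correlated exogenous and three endogenous latent variables, four
indicators each with standardized loadings 0.8/0.7/0.6/0.5, nine structural
paths in [0.1, 0.6]), an ordinal data generator whose threshold sets hit
prescribed skewness/kurtosis targets for 4–7 response categories, a
structural misspecification operator (drop the four weakest paths), recovery
metrics (relative bias, relative RMSE, MAD, η² ANOVA screening), and a
seeded simulation harness over the 80-condition design. It is aimed at
methodologists who want to rerun, extend, or audit this class of
estimator-comparison study rather than fit models to empirical data.

All estimators are scikit-learn-style classes (`GscaAls`, `CsaMl`,
`CsaDwls`) with `fit(X)` and trailing-underscore fitted attributes;
module-level functions (`fit_gsca`, `fit_ml`, `fit_dwls`, …) are thin
wrappers over the same code.

## Worked example

Generate one dataset from the population model (n = 500, five symmetric
categories), fit all three estimators, and compare a few estimates with the
population truths:

```python
import numpy as np
from ordsem import (build_population_model, generate_continuous, discretize,
                    threshold_set, truth_table, GscaAls, CsaMl, CsaDwls)

spec, params = build_population_model()
data = discretize(generate_continuous(params, 500, seed=7),
                  threshold_set(5, "symmetric"))

for name, est in [("gsca_als", GscaAls(spec)), ("csa_ml", CsaMl(spec)),
                  ("csa_dwls", CsaDwls(spec))]:
    fit = est.fit(data)
    e = fit.estimates_
    print(f"{name:9s} lam_i1={e['lam_i1']:.3f} gamma11={e['gamma11']:.3f} "
          f"beta21={e['beta21']:.3f} phi={e['phi']:.3f}")
print(f"truth     lam_i1={truth_table(params)['lam_i1']:.3f} "
      f"gamma11=0.600 beta21=0.400 phi=0.300")
```

Output:

```
gsca_als  lam_i1=0.819 gamma11=0.442 beta21=0.387 phi=0.174
csa_ml    lam_i1=0.764 gamma11=0.568 beta21=0.553 phi=0.257
csa_dwls  lam_i1=0.804 gamma11=0.569 beta21=0.549 phi=0.248
truth     lam_i1=0.800 gamma11=0.600 beta21=0.400 phi=0.300
```

The pattern is the phenomenon under study: treating ordinal codes as
continuous attenuates the ML loadings (0.764 vs 0.800), the polychoric-based
DWLS engine restores them (0.804), and the component-based GSCA structural
paths sit systematically below the factor-based truths while its composite
loadings land near the population values.

A reduced simulation over a few design cells, from the command line:

```bash
ordsem simulate --conditions cor_k5_sym_n200,mis_k5_sym_n200 \
                --reps 25 --seed 1 --out results/demo
```

which writes long-format estimates, a run log with per-replication
convergence status, RB_a/RMSE_a recovery tables, replication-level MAD and
η² ANOVA tables as CSV. `--full` switches to the 500-replication profile
(40,000 replications over the 80-cell grid).

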