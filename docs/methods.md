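# Methods

`ordsem` is a Monte Carlo laboratory for a single, fixed question: how well do
three estimation traditions for structural equation models recover known
population parameters when the observed indicators are ordinal? The three
engines are component-based GSCA fitted by alternating least squares
(`gsca_als`), and factor-based covariance structure analysis fitted either by
normal-theory maximum likelihood on the Pearson covariance of the ordinal
codes (`csa_ml`) or by diagonally weighted least squares on polychoric
correlations — the point-estimation core of WLSMV (`csa_dwls`).

## Population model

The data-generating model has five latent variables: two exogenous factors
(`xi1`, `xi2`, correlated at ϕ) and three endogenous factors (`eta1`–`eta3`)
linked by nine directed paths — six γ paths from exogenous sources and three β
paths between endogenous factors. Every latent variable carries four
indicators with standardized loadings 0.8, 0.7, 0.6, 0.5, so uniquenesses are
1 − λ² and all indicators are standard normal before discretization.
Structural residual variances are solved recursively (the endogenous graph is
acyclic) so every latent variable has exactly unit variance; population values
are therefore the standardized truths used by all recovery metrics, with no
post-hoc rescaling.

Default path values (overridable via config): γ11 = 0.6, γ12 = 0.5,
γ21 = 0.4, γ22 = 0.2, γ31 = 0.1, γ32 = 0.1, β21 = 0.4, β31 = 0.1, β32 = 0.3,
ϕ = 0.3. All paths lie in [0.1, 0.6], and the four weakest edges
(γ22, γ31, γ32, β31) are exactly the ones removed by the structural
misspecification operator, which leaves the measurement model untouched.
ϕ is implemented as the correlation between the two *exogenous* factors: a
single correlation among exogenous latents is the standard layout for this
Γ/ϕ notation, whereas a free correlation between endogenous factors would
conflict with the recursive structural equations.

## Ordinal data generation

Continuous indicator data follow the common-factor model (latent draws from
the implied latent covariance, plus independent uniqueness noise), then each
column is cut at K − 1 thresholds on the standard-normal latent-response
scale, K ∈ {4, 5, 6, 7}, scored 1..K. Two stored threshold shapes per K define
the distribution conditions:

* symmetric — skewness exactly 0 (enforced structurally by τ_j = −τ_{K−j}),
  excess kurtosis −0.485;
* asymmetric — skewness −1.385, excess kurtosis +1.165 (negative skew: mass
  piled on the high categories, as in typical Likert data).

Kurtosis is excess (Fisher) kurtosis throughout; the targets are the
midpoints of the narrow per-condition windows the study conditions describe
(−0.49 to −0.48, −1.39 to −1.38, +1.14 to +1.19). The moment targets leave
the thresholds underdetermined for K > 2, so the solver picks the
maximum-entropy threshold set subject to the moment constraints (SLSQP with
deterministic multistart): this keeps every category populated instead of
letting the optimizer park thresholds in the tails, and makes the stored sets
reproducible. Residuals above 5·10⁻³ on a matched moment raise an
"unattainable targets" error. All 20 indicators share one threshold set per
condition, and category-count conditions use independent draws rather than
paired ones; both choices are recorded here because the study conditions do
not prescribe them.

What the generator deliberately does not emulate: per-indicator threshold
heterogeneity, non-normal latent responses, missing data, or any
component-based (rather than common-factor) data-generating process. Passing
tests therefore speak to recovery under a factor-analytic world with clean
marginals — not to robustness against those further complications. In
particular, generating from the factor model is known to disadvantage GSCA's
loadings, which is part of the phenomenon under study.

## GSCA-ALS

With the weighted relation γ = Wz, V = [I; W] and A = [C; B], the criterion
φ = Σᵢ ‖Vzᵢ − AWzᵢ‖² is minimized under the constraint that every component
score vector has unit sample variance (Σγ² = N; columns are standardized with
denominator N). The two ALS half-steps are both exact:

* A-step — each indicator regresses on its own component and each endogenous
  component on the components entering its equation (ordinary least squares
  row by row);
* W-step — for one component, every criterion term containing γ_d is collected
  into φ(w_d) = Σ_m ‖t_m − α_m Z w_d‖² with ‖Z w_d‖² = N. On that sphere the
  quadratic term is constant, so the constrained minimizer is the projection
  of Σ α_m t_m onto the block's indicator span, rescaled to the sphere. This
  makes the criterion provably non-increasing (asserted over 100 random
  datasets in the tests, and against a brute-force minimizer on a fixture).

Numerical choices: equal weights per block at initialization (deterministic;
the estimator itself uses no randomness), Gauss–Seidel component updates,
convergence when the relative drop of φ falls below 1e−6, cap 500 cycles.
Component sign indeterminacy is resolved by forcing a positive correlation
with the block's first indicator, matching the all-positive truths.
Bootstrap standard errors are out of scope: the study compares point
estimates only.

## CSA-ML

The ordinal codes are treated as continuous: S is their Pearson covariance
(denominator n − 1) and F_ML = ln|Σ(θ)| + tr(SΣ⁻¹(θ)) − ln|S| − r is minimized
by L-BFGS-B with an analytic gradient (dF = tr[Σ⁻¹(Σ − S)Σ⁻¹ dΣ] chained
through the structural algebra; verified against finite differences).
Identification fixes the exogenous factor variances at 1; uniquenesses and
structural residual variances are carried on a log scale and ϕ on an atanh
scale, so every iterate is algebraically proper. Start values: loadings
0.5·√s_jj, paths and ϕ at 0, uniquenesses 0.75·s_jj, unit residual variances.

Because all 20 loadings are free while endogenous factor variances are
determined by paths and residual variances, each endogenous factor carries a
scale-indeterminacy ridge (λ·c, γ·c, ψ·c² trade off). The completely
standardized solution is invariant along the ridge and is what the metrics
consume; the Heywood screen is likewise computed on ridge-invariant ratios
(uniqueness over implied indicator variance, residual variance over implied
latent variance), flagging a solution as improper when a ratio collapses
below 5·10⁻³ — the log-scale image of a zero-or-negative variance estimate —
or when the implied latent covariance is not positive definite.

Convergence accounting: a replication is non-converged when the optimizer
fails or hits its 10,000-evaluation cap, and additionally when the sample
size does not exceed the free-parameter count of the mean-and-covariance
model (73 under the correct specification, 69 misspecified, intercepts
included). The latter admissibility precondition mirrors how standard SEM
software refuses models with more parameters than observations and is what
makes every n = 50 ML replication inadmissible while leaving n ≥ 100
untouched. Improper and non-converged replications are both excluded from
recovery metrics.

## CSA-DWLS (WLSMV point estimates)

Olsson's two-step method: thresholds from univariate margins (normal
quantiles of cumulative proportions; an empty extreme category is collapsed
into its neighbor and the event recorded, never silently dropped), then one
bounded likelihood maximization per indicator pair over ρ ∈ (−0.999, 0.999)
with thresholds fixed. Rectangle probabilities come from an Owen's-T-based
bivariate normal CDF (vectorized; validated against scipy's generic
multivariate normal CDF to 1e−10), and ∂p/∂ρ from Plackett's identity.

The weight matrix uses only diagonal entries, as delta-method asymptotic
variances: c(1−c)/(n·φ(τ)²) for thresholds and the inverse single-parameter
Fisher information for each polychoric. The DWLS minimizer is invariant to
any positive rescaling of these weights (asserted in tests), which bounds the
sensitivity to the exact variance estimator. Thresholds are free parameters
fitted at their first-stage values (delta parameterization), so they drop out
of F_DWLS and only the 190 correlations carry model structure. The fitted
parameters — 20 loadings, the paths, ϕ — live directly on the standardized
latent-response scale with residual variances solved for unit latent
variances; estimates need no further standardization.

Accounting: improper when the assembled polychoric matrix is not positive
definite or the solution implies a negative uniqueness or residual variance;
non-converged when any pair sits at the correlation bound, a weight is
non-finite, or the optimizer fails. The mean-and-variance χ² adjustment and
standard errors are out of scope — they do not alter the point estimates
being compared.

Compared with the convergence rates commercial SEM software produces for
designs of this size, this accounting matches closely at n ≥ 100 but is
slightly more permissive at n = 50: roughly 2–20% of n = 50 WLSMV
replications (condition-dependent) pass every admissibility check here,
where such software typically fails all of them. No principled criterion we
examined separates those survivors without also contradicting the observed
n = 100 behavior, so the discrepancy is left visible rather than patched
with an ad-hoc cutoff.

## Recovery metrics and the ANOVA screen

Per parameter over converged-and-proper replications: RB = 100·mean of
(θ̂ − θ)/θ and RMSE = √(mean of ((θ̂ − θ)/θ)²) — the root of the mean squared
*relative* deviation — averaged separately over loadings and paths (RB_a,
RMSE_a). Under misspecification the omitted paths are simply not parameters
of the fitted model, so metrics run over the 20 loadings and 5 retained
paths, against unchanged population truths. Within one replication
MAD = mean |θ̂ − θ| is computed separately for loadings and paths and is the
ANOVA outcome, analyzed at replication level (a cell-mean variant is
available via aggregation of the returned table) with the five design
factors — estimator, misspecification, distribution shape, category count,
sample size — and all interactions up to five-way. Unbalanced cells (CSA
non-convergence at small n) are handled by sequential (type I) sums of
squares in that documented factor order.

The effect table reports both η² = SS_eff/SS_total, whose sum over effects is
bounded by one, and partial η² = SS_eff/(SS_eff + SS_err). Effect sizes of
this kind reported in the simulation literature are customarily partial η²
(headline values in such studies often sum beyond what a classical
decomposition could jointly allow), so cross-study comparisons should use
the partial column; both come from the same sequential decomposition.

## Orchestration and problem sizes

The 2 × 4 × 2 × 5 grid (misspecification × categories × shape × n) yields 80
conditions; the full profile plans 500 replications each (40,000 total), and
a reduced 50-replication profile is the default. Per replication one dataset
is drawn and handed bytewise-identically to every requested estimator; seeds
derive from (base seed, condition index, replication index) via SeedSequence
spawning, so results are reproducible independently of worker count, and
every attempt is recorded in a run log with status
(converged / nonconverged / improper / degenerate) and timing. Estimator
failures are contained per replication and never abort a run.

The shipped test suite runs deliberately reduced problem sizes chosen as
its defaults: the η² screen at 10 replications per condition, the
misspecification comparison on one category/shape cell at 15 replications,
Monte Carlo oracles at 10⁵–10⁶ draws, and the large-sample consistency checks
at n = 100,000. The full-scale study is a single flag away
(`ordsem simulate --full`).

A caution on the ANOVA screen: the absolute magnitudes of the path-recovery
effect sizes depend strongly on the true path values, which are configurable
(the defaults are one admissible choice within the stated [0.1, 0.6] range).
With the defaults, the estimator-by-misspecification contrast on path MAD is
present and correctly signed at moderate-to-large n, but it is modest
relative to replication noise; stronger true paths or latent correlations
amplify the distortion that structural misspecification induces in the
factor-based engines and hence the associated effect sizes.

## Known limitations

* The convergence accounting reproduces the qualitative behavior of
  standard SEM software, not any particular implementation's internals;
  exact non-convergence percentages (especially the n = 50 WLSMV boundary)
  can differ in the few-percent range, and the ML Heywood screen flags more
  small-n solutions than commercial implementations typically report.
* GSCA is evaluated on factor-generated data, which biases its loading
  estimates upward by construction; this is the designed comparison, not an
  artifact, but it means loading results say nothing about GSCA on
  component-generated data.
* Only this five-factor template is supported (pattern edits via
  misspecification); no mean structures, no per-indicator thresholds, no
  standard errors or fit statistics.
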