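# Methods

`multirct` implements and compares four analysis strategies for two-arm
randomised trials with multiple correlated primary outcomes and missing
outcome data, together with the synthetic-data machinery needed to study
their familywise error rate (FWER), disjunctive power and bias by
simulation.

## Data-generating model

Outcomes for participant *i* follow the latent-normal model

    Y_i = β₀ + β₁ x_i + ε_i,   ε_i ~ N(0, R(ρ)),

with `x_i ∈ {0, 1}` the arm indicator (equal allocation, deterministic
n/2 per arm), unit error variances and an equicorrelated error matrix
`R(ρ)` (all off-diagonals ρ, admissible iff ρ > −1/(m−1)).  Continuous
effect sizes are therefore standardised mean differences.  Binary outcomes
are the latent values dichotomised at zero, so a latent shift of
Φ⁻¹(0.65) ≈ 0.385 moves a 50% control event rate to 65%, and ρ is the
*tetrachoric* (latent) correlation of the resulting binary pair, not the
phi coefficient.  Mixed panels return the continuous columns on the latent
scale and threshold the rest.

Default study conditions follow the benchmark factorial design: n = 260
for continuous and mixed scenarios and n = 340 for binary scenarios (the
single-outcome design sizes at α = .05 and 80% power for effects 0.35 and
50%→65% respectively), ρ ∈ {0, .2, .4, .6, .8}, equal effects 0.35 (all
outcomes, including the binary member of mixed pairs, on the latent scale)
or varying effects (0.2, 0.4) / (0.1, 0.2, 0.3, 0.4), and 10,000
replicates at full scale.

### Missingness mechanisms

* **MCAR** — independent Bernoulli deletion at the per-outcome target rate.
* **MAR (on arm)** — per-arm deletion probabilities with
  `p_control = 1.5 × p_intervention` and mean equal to the target; the
  "1.5 times more likely" factor is read as a probability ratio and is
  configurable.
* **MNAR** — participants are sorted in ascending order of the complete
  value of the targeted outcome, split into quartile groups (sizes
  differing by at most one, larger groups first; ties broken by original
  index) and deleted at quartile-specific rates taken from a fixed
  schedule whose rows average to the overall rate (e.g. 50% overall =
  (0, 25, 75, 100)% per quartile).  Each targeted outcome is sorted by its
  own values, so "overlapping" MNAR applies the schedule per outcome
  independently.

Cross-outcome dependence of the missingness indicators defaults to 0
(independent per outcome) and is exposed as a Gaussian-copula correlation
parameter.  The complete matrix is retained on the returned object for
bias oracles; estimators only see the masked data.

## Analysis methods

**UV** — per-outcome complete-case analysis: OLS for continuous outcomes
(two-group closed form; t reference with n−2 df, matching standard linear
regression output; Wald z optional) and maximum-likelihood probit for
binary outcomes (Newton on the exact log-likelihood, gradient tolerance
1e-8; Wald z; complete separation flagged as nonconvergence).

**MI+UV** — multiple imputation by chained equations run separately within
each arm (equivalent to conditioning on arm), M = 40 imputations, 5 cycles
each, initial fill drawn from the observed marginals.  Continuous columns
are imputed by type-1 predictive mean matching (PMM) with 5 donors —
deliberately the default of the standard chained-equations software, and
the choice that reproduces the benchmark behaviour: with weakly
predictive imputation models PMM makes Rubin's total variance
`T = W + (1+1/M)B` markedly conservative (we measure pooled SE ≈ 0.18–0.21
against an empirical sampling SD of ≈ 0.15–0.19 at 30/50% MCAR and ρ = 0),
which depresses both FWER (≈ 0.03) and disjunctive power, exactly the
pattern the comparison is about.  A well-calibrated Bayesian normal-linear
imputer (`continuous_method="norm"`) is provided; with it MI power at ρ=0
is close to complete-case power and the conservativeness disappears.
Binary columns use Bayesian logistic draws, intentionally mismatched with
the probit generator (a probit imputer exists for sensitivity checks).
Pooling uses Rubin's rules with Barnard–Rubin degrees of freedom
(complete-data df = n − 2 for continuous outcomes, ∞ otherwise).

**MM** — the joint multivariate model.  For continuous outcomes this is
the multivariate normal `Y ~ N(β₀ + β₁x, Ω)` with unstructured Ω, fitted
by direct maximisation of the observed-data log-likelihood (each
participant contributes the marginal density of their observed subvector;
valid under MAR).  Ω is parameterised by its log-Cholesky factor, the
likelihood and analytic gradient are evaluated from per-(arm, pattern)
sufficient statistics (O(1) per evaluation after one pass over the data),
optimisation is L-BFGS-B followed by Newton polishing to gradient norm
< 1e-6, and standard errors come from the inverse numerical Hessian.  An
EM fit of the same likelihood is included as an algorithmically
independent cross-check.  Per-outcome Wald statistics use a t reference
with (cases observed for that outcome − 2) df, mirroring the univariate
comparator; z is optional.  For two binary outcomes the MM role is played
by a bivariate probit with latent correlation (rectangle probabilities via
a 64-node Gauss–Legendre rule on the single-integral form of the bivariate
normal CDF, accurate to ~1e-12 for |ρ| ≤ 0.99); because arm is the only
covariate the likelihood reduces to per-arm cell counts.  For a mixed pair
the joint latent-normal likelihood combines a normal margin with the
conditional probit Φ(±(η₂ + (ρ/σ₁)(y₁−μ₁))/√(1−ρ²)).  Fits with |ρ̂| at
the 0.99 boundary, failed optimisations or non-invertible Hessians are
flagged; simulation summaries exclude and count such replicates, and FWER
and power denominators use converged replicates only.

**LV** — a shared-latent-variable model: one normal random effect
`l ~ N(0, σ_l²)` enters every linear predictor (loading fixed at 1 for the
first outcome, free λ_j otherwise), inducing all cross-outcome
correlation.  σ_l² is fixed for identifiability at 0.8 for continuous and
mixed panels and 1.0 for all-binary panels.  The marginal likelihood
integrates over *l* by 10-node Gauss–Hermite quadrature; by default the
nodes are recentred at each participant's posterior mode and rescaled by
the curvature (adaptive), which makes 10 nodes accurate to ~1e-7 — the
fixed-node rule is retained as an option but fails a 1e-4 stability check
against a 40-node reference on realistic fixtures.  Binary effect
estimates are additionally rescaled to the marginal probit scale by
dividing by √(λ²σ_l² + 1); the square root makes the rescaling reduce to
the identity at λ = 0 and match the standard marginal-probit attenuation.
The rescaling is applied to estimate, SE and CI jointly (λ uncertainty
ignored), so p-values equal the raw Wald test.

**Factorisation** — for one continuous and one binary outcome, the
marginal-probit × conditional-linear decomposition: probit of Y₂ on arm,
then OLS of Y₁ on arm and the centred Y₂ − Φ(β̂₀₂+β̂₁₂x); the coefficient τ
on the centred term measures the association.  Implemented as an estimator
only — it is not part of the simulation grid.

## Multiplicity and summaries

Per-outcome p-values within each method are Holm step-down adjusted; the
disjunctive decision rejects if any adjusted p < α = 0.05.  A scenario
summary reports the rejection proportion (FWER under the null, disjunctive
power otherwise), its binomial Monte Carlo standard error
√(p̂(1−p̂)/R_converged), per-outcome bias (mean estimate − truth),
empirical SE (SD of estimates) and convergence counts.  Design-stage
helpers implement the classical two-proportion sample size (0.50 vs 0.65,
α = .05, 80% power → 170/arm, 340 total) and the normal-approximation
continuous formula (ES = 0.35 → 129/arm; the benchmark scenario constant
260 is configuration, not recomputed, since the rounding convention behind
it is not derivable).

## Pipeline and reproducibility

`run_scenario` executes one factorial cell.  Replicate r draws its
generator, missingness and imputation randomness from an independent
substream seeded by (scenario seed, r), and every method within a
replicate analyses the identical dataset (a paired design, chosen to
remove between-method simulation noise from the power ratios).  Results
are therefore bitwise reproducible from (config, seed) and invariant to
the parallel worker count.  The scenario grid enumerates the tabulated
cells: complete / MCAR-low / MCAR-high / MAR-low / MAR-high × ρ × {null,
equal} for two-outcome continuous, binary and mixed panels; MNAR cells
(continuous, equal effects) and four-continuous-outcome cells are
opt-ins.  The MM model is never run for four binary outcomes, where it
routinely fails to converge.

## Problem sizes

Full-scale runs use 10,000 replicates (MCSE ≤ 0.005 for a proportion).
The acceptance script uses 10,000 replicates for all closed-form-fast
cells and 2,000 for the multiple-imputation cell (MCSE ≈ 0.011 at
p ≈ 0.5); the test suite additionally uses 2,000-replicate runs for the
MNAR bias contrast and a few hundred replicates for parameter-recovery
checks, with tolerances set at three Monte Carlo standard errors of the
quantity concerned.

## What the generator does and does not emulate

The generator reproduces the benchmark study conditions exactly:
equicorrelated unit-variance normal errors, probit-threshold binary
outcomes, equal allocation, arm as the only covariate, and the three
missingness mechanisms above.  It does not emulate skewed or heavy-tailed
continuous outcomes, unequal allocation, baseline covariates,
cluster/centre structure, or missingness driven by auxiliary variables —
so passing tests certify the estimators under the stated latent-normal
conditions, not robustness to their violation.

## Numerical choices and degenerate inputs

Noiseless outcomes give SE = 0 and p ∈ {0, 1} by convention.  Probit fits
refuse one-class outcomes and flag separated arms.  Imputation requires at
least one observed value per outcome per arm.  MNAR targets must be keys
of the quartile schedule; MAR targets whose control-arm probability would
exceed 1 are rejected.  Pairwise-complete starting covariances are
eigenvalue-clipped to be positive definite.  The equicorrelation bound
ρ > −1/(m−1) is enforced with an explicit message.

## Known limitations

MI behaviour at weak correlation depends on the imputation engine (PMM vs
normal-linear) more than on any other choice in the package; both engines
are exposed so the sensitivity is one keyword away.  Small-sample SEs of
the ML fits are mildly optimistic (ML, not REML, covariance estimates);
the t references above absorb most, not all, of this.  The LV rescaling
ignores the sampling variability of λ̂.  The bivariate-probit and
mixed-pair MM fits cover pairs only; the continuous MM handles any m.
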