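# multirct

Analysis of **multiple correlated primary outcomes** in two-arm randomised
controlled trials with **missing outcome data** — and the simulation
machinery to compare the competing strategies.

Trials in areas such as mental health, stroke or COPD often specify several
primary outcomes because no single measure captures the disease process.
Analysing each outcome separately (UV) is simple but discards both the
correlation between outcomes and every participant with a missing value for
that outcome; multiple imputation before univariate analysis (MI+UV),
joint multivariate models (MM) and shared-latent-variable models (LV) all
try to do better.  This package implements all four, plus the
factorisation model for mixed continuous–binary pairs, for
biostatisticians who want to analyse such a trial or to study the
frequentist properties of these choices by simulation.

## The models

For participant *i*, outcome *j*, with arm indicator `x_i` and effect
`β₁j`:

* **UV** — per-outcome complete-case linear regression
  `Y_ij = β₀j + β₁j x_i + ε_ij` (continuous) or probit regression
  `P(Y_ij = 1) = Φ(β₀j + β₁j x_i)` (binary).
* **MI+UV** — chained-equations multiple imputation by arm (M = 40;
  predictive mean matching for continuous columns, Bayesian logistic draws
  for binary), then UV on each completed set and Rubin's rules
  `T = W + (1 + 1/M)B`.
* **MM** — the joint model `Y_i ~ N(β₀ + β₁ x_i, Ω)` with unstructured Ω,
  fitted by observed-data maximum likelihood so partially observed
  participants contribute their marginal density (valid under MAR);
  bivariate-probit and mixed latent-normal analogues for binary / mixed
  pairs.
* **LV** — a shared normal random effect `l ~ N(0, σ_l²)` (variance fixed
  for identifiability) in every linear predictor, integrated out by
  adaptive 10-node Gauss–Hermite quadrature; binary effects rescaled by
  `1/√(λ²σ_l² + 1)` to the marginal probit scale.

Per-outcome p-values are Holm-adjusted; the package estimates the
familywise error rate (FWER) under the global null and the **disjunctive
power** (probability of detecting at least one true effect) otherwise,
with per-outcome bias, empirical SEs and Monte Carlo standard errors.

The synthetic-data generator draws equicorrelated latent-normal outcomes
(binary outcomes thresholded at zero) and imposes MCAR, arm-dependent MAR
(control arm 1.5× more likely missing) or value-dependent MNAR
missingness (quartile-based deletion rates rising with the outcome
value).  See `docs/methods.md` for the full model and design notes.

## Worked example

One trial, strongly correlated outcomes, half of outcome 2 missing
(`examples/02_univariate_vs_multivariate.py`):

```text
method  outcome  estimate     se  p_value  n_used
linear        1    0.4348 0.1168   0.0002     260
linear        2    0.4773 0.1711   0.0053     120
    mm        1    0.4348 0.1163   0.0002     260
    mm        2    0.5404 0.1287   0.0001     120
    lv        1    0.4348 0.1163   0.0002     260
    lv        2    0.5404 0.1287   0.0000     120
```

All methods target the standardised effect 0.35.  For the fully observed
outcome 1 the joint fits collapse to OLS; for outcome 2 they exploit the
ρ = .8 correlation with outcome 1, so their standard error (0.129) beats
the complete-case one (0.171).

A small operating-characteristics run
(`examples/04_power_simulation.py 300`; 10,000 replicates reproduce
benchmark precision):

```text
scenario continuous2_MCAR-high_rho0.8_equal, 300 replicates
method metric  proportion   mcse  relative_power_vs_uv  n_excluded
    uv  power      0.6433 0.0277                1.0000           0
 mi_uv  power      0.7367 0.0254                1.1451           0
    mm  power      0.7100 0.0262                1.1036           0
    lv  power      0.7191 0.0260                1.1177           1
```

With 30%/50% missingness and ρ = .8 the joint models and MI recover the
disjunctive power that complete-case analysis loses (relative power ≈ 1.1).
The same machinery is scriptable from the shell:

```bash
multirct grid --outcome-type continuous
multirct simulate --outcome-type continuous --rho 0.8 --mechanism MCAR \
    --level high --reps 1000 --seed 7 --out results.csv
multirct analyze mytrial.csv --method mm
```

`examples/` also covers trial generation and MNAR (01), multiple
imputation diagnostics (03) and the MNAR bias-versus-correlation curve
(05).

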