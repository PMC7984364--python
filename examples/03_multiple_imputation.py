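"""Multiple imputation by chained equations with Rubin's-rules pooling.

Imputes a trial with 30%/50% completely-at-random missingness (40
imputations, by arm), analyses each completed data set per outcome and
pools the estimates; prints the within/between variance decomposition.
"""

from multirct import MissingnessPlan, OutcomeModel, apply_missingness, fit_mi_uv, fit_uv, simulate

model = OutcomeModel(effects=[0.35, 0.35], rho=0.4)
trial = apply_missingness(
    simulate(model, 260, seed=3), MissingnessPlan("MCAR", [0.3, 0.5]), seed=4
)

uv = fit_uv(trial)
mi = fit_mi_uv(trial, M=40, seed=5)
for j, (u, p) in enumerate(zip(uv, mi), start=1):
    print(f"outcome {j}:")
    print(f"  complete-case : {u.estimates[0]:+.4f} (SE {u.se[0]:.4f}, n={u.n_used[0]})")
    print(
        f"  MI (M=40)     : {p.estimates[0]:+.4f} (SE {p.se[0]:.4f}, "
        f"W={p.nuisance['within']:.4f}, B={p.nuisance['between']:.4f}, "
        f"df={p.nuisance['df']:.0f})"
    )
print(
    "\nThe pooled total variance W + (1+1/M)B reflects both sampling noise and\n"
    "imputation uncertainty; with weakly correlated outcomes the imputation\n"
    "model predicts poorly and MI cannot beat the complete-case analysis."
)
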