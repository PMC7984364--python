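"""Bias of the joint model under value-dependent (MNAR) missingness.

For two continuous outcomes with 50% MNAR missingness in outcome 1, the
multivariate-normal model assumes data are missing at random.  Its estimate
for outcome 1 is biased, but the bias shrinks as the correlation with the
fully observed outcome grows — the observed outcome partially stands in for
the selectively missing one.  Writes a bias-versus-correlation figure.
"""

import numpy as np

from multirct import MissingnessPlan, OutcomeModel, apply_missingness, fit_mm_continuous, simulate

REPS = 300
rhos = [0.0, 0.2, 0.4, 0.6, 0.8]
bias = []
for rho in rhos:
    model = OutcomeModel(effects=[0.35, 0.35], rho=rho)
    plan = MissingnessPlan("MNAR", [0.5, 0.0])
    est = []
    for r in range(REPS):
        rng = np.random.default_rng(np.random.SeedSequence([99, r]))
        trial = apply_missingness(simulate(model, 260, rng), plan, rng)
        fit = fit_mm_continuous(trial)
        if fit.converged:
            est.append(fit.estimates)
    est = np.asarray(est)
    bias.append(est.mean(axis=0) - 0.35)
    print(
        f"rho={rho:.1f}: bias outcome1 = {bias[-1][0]:+.3f}, "
        f"outcome2 = {bias[-1][1]:+.3f} ({len(est)} converged reps)"
    )
bias = np.asarray(bias)
print(
    "\nBias for the MNAR-affected outcome 1 shrinks with rho but never reaches\n"
    "zero; outcome 2 (fully observed) stays approximately unbiased throughout."
)

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(rhos, bias[:, 0], "o-", label="outcome 1 (50% MNAR)")
    ax.plot(rhos, bias[:, 1], "s-", label="outcome 2 (complete)")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("correlation between outcomes")
    ax.set_ylabel("bias of the joint-model estimate")
    ax.legend()
    fig.tight_layout()
    fig.savefig("mnar_bias.png", dpi=120)
    print("wrote mnar_bias.png")
except ImportError:
    pass
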