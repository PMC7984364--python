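"""Fit the competing estimators to one trial with nonoverlapping missingness.

With strongly correlated outcomes (rho=.8) and half of outcome 2 missing,
the joint multivariate-normal (MM) and shared-latent-variable (LV) models
borrow strength from the observed outcome, giving smaller standard errors
for outcome 2 than the complete-case univariate fit.
"""

import pandas as pd

from multirct import (
    MissingnessPlan,
    OutcomeModel,
    apply_missingness,
    fit_lv,
    fit_mm_continuous,
    fit_uv,
    simulate,
)

model = OutcomeModel(effects=[0.35, 0.35], rho=0.8)
trial = apply_missingness(
    simulate(model, 260, seed=1), MissingnessPlan("MCAR", [0.0, 0.5]), seed=2
)

rows = []
for j, fit in enumerate(fit_uv(trial), start=1):
    frame = fit.to_frame()
    frame["outcome"] = j  # single-outcome fits are numbered by column
    rows.append(frame)
for fit in (fit_mm_continuous(trial), fit_lv(trial)):
    rows.append(fit.to_frame())
table = pd.concat(rows, ignore_index=True)
print(table[["method", "outcome", "estimate", "se", "p_value", "n_used"]].to_string(
    index=False, float_format=lambda v: f"{v:.4f}"
))
print(
    "\nFor outcome 2 (50% missing) the joint models use all 260 participants\n"
    "and their SE is below the univariate complete-case SE; the estimates all\n"
    "target the same standardised effect of 0.35."
)
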