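"""Estimate familywise error and disjunctive power for one scenario cell.

Runs a reduced replicate count (500) of the scenario 'two continuous
outcomes, rho=.8, 30%/50% MCAR missingness' for all four analysis methods
with Holm adjustment, and prints the method comparison.  Increase --reps to
10,000 to reproduce benchmark-precision values.
"""

import sys

from multirct import ScenarioConfig, run_scenario, write_results

reps = int(sys.argv[1]) if len(sys.argv) > 1 else 500

config = ScenarioConfig(
    outcome_type="continuous", rho=0.8, effect="equal",
    mechanism="MCAR", level="high", n_reps=reps, seed=12,
)
print(f"scenario {config.scenario_id}, {reps} replicates, methods {config.methods}")
summaries = run_scenario(config, progress=True)
df = write_results(summaries)
print(df[["method", "metric", "proportion", "mcse", "relative_power_vs_uv",
          "n_excluded"]].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nWith strong correlation and heavy missingness the joint MM model and\n"
    "MI recover power that the complete-case univariate analysis loses."
)
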