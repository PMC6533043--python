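"""Estimate how emotion and network position shape time to dropout.

Fits Aalen's additive hazards model on the survival sample (users active
past the first observation), both plainly and with the control-function
IV extension (followee-mean emotion and centrality as instruments,
first-stage residuals entering as extra time-varying covariates).
Reports mean coefficients (per day) with case-bootstrap 95% intervals.
"""

from attrical.pipeline import estimation_table, measure, survival_estimates
from attrical.simulate import SimulationConfig, simulate_panel

panel = simulate_panel(SimulationConfig(n_users=2000, seed=42))
meas = measure(panel)
table = estimation_table(panel, meas)
res = survival_estimates(panel, meas, table, scheme="identical", pi=30.0,
                         n_boot=200, seed=7)

print(f"survival sample n = {res['n']}, events = {res['n_events']}")
for kind in ("standard", "iv"):
    fit = res[kind]
    for var in ("emotion", "centrality"):
        est = fit.mean_coefficients[var]
        lo, hi = fit.ci_95.loc[var, ["lower", "upper"]]
        print(f"{kind:>8} {var:>10}: {est:+.5f}/day  (95% CI {lo:+.5f} to {hi:+.5f})")
print("A positive emotion coefficient raises the dropout hazard (shorter "
      "participation); the negative centrality coefficient means users in "
      "deeper network cores persist longer.")
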