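"""Estimate the effect of emotion on the probability of dropout.

Fits the linear-probability model by OLS and by two-stage least squares
with the followee-mean emotion instrument, controlling for the full
covariate set. Confounding is planted in the generator, so OLS is
attenuated while 2SLS recovers a larger effect; the first-stage F and
Wu-Hausman diagnostics quantify instrument strength and endogeneity.
"""

from attrical.pipeline import estimation_table, linear_estimates, measure
from attrical.simulate import SimulationConfig, simulate_panel

panel = simulate_panel(SimulationConfig(n_users=2000, seed=42))
meas = measure(panel)
table = estimation_table(panel, meas)
fits = linear_estimates(table)

for name, fit in fits.items():
    beta = fit.params["emotion"]
    se = fit.se["emotion"]
    print(f"{name.upper():>4}: emotion effect on dropout probability = "
          f"{beta:+.4f} (robust se {se:.4f}), n = {fit.n_obs}")

F = fits["tsls"].first_stage_F["emotion"]
H, p = fits["tsls"].wu_hausman
print(f"first-stage F = {F:.1f} (> 10 means a strong instrument)")
print(f"Wu-Hausman H = {H:.2f}, p = {p:.3g} "
      "(rejection indicates emotion is endogenous)")
print("A positive effect means users with more positive language are more "
      "likely to stop posting; 2SLS exceeding OLS reflects confounding "
      "that biases the naive estimate toward zero.")
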