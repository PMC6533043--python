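# attrical

Causal estimation of the determinants of attrition (dropout) in online
communities, for researchers studying engagement in peer-to-peer health
communities from observational social-media data.

Observed user attributes — emotional tone of posts, position in the
follow network — are correlated with dropping out, but unobserved
factors (treatment episodes, offline life events) plausibly drive both,
so naive regressions are biased. `attrical` implements the
instrumental-variables strategy that uses *followee-averaged* attributes
as instruments: what a user's followees feel and how central they are
influences the user (relevance, via peer influence and homophily), but
plausibly affects the user's dropout only through the user's own
attributes once followees' own attrition is controlled (exclusion).

Two outcome models are estimated:

- **Linear probability** for the binary dropout status
  `Y = β₁X₁ + β₂X₂ + u`, with the endogenous emotion `X₁` instrumented
  by the followee mean `Z̄` in two-stage least squares (HC1 robust
  inference, first-stage F, Wu-Hausman endogeneity test, cross-
  specification Wald equality).
- **Aalen additive hazards** for the interval-censored time to dropout,
  `h_i(t) = b₀(t) + Σ_k b_k(t)x_ik`, estimated by least-squares
  increments of the cumulative coefficients `B_k(t)`; the IV variant is
  a control-function estimator that adds first-stage residuals as extra
  time-varying covariates. Confidence intervals are case-bootstrap.

Measurement is part of the pipeline: a pluggable lexicon scorer assigns
each tweet an integer sentiment in [−4, 4] (user emotion = mean over
original tweets), in-coreness on the who-follows-whom digraph measures
network position, and censoring schemes (identical and personalized
silence thresholds) construct the survival outcomes. Because community
platform data cannot be redistributed, the package ships a synthetic
community generator with planted homophily, peer-coupled emotions, a
hidden confounder, hazard-driven dropout and topic-conditioned hashtags,
so every stage is testable end to end against known ground truth.

## Worked example

```python
from attrical.pipeline import estimation_table, linear_estimates, measure
from attrical.simulate import SimulationConfig, simulate_panel

panel = simulate_panel(SimulationConfig(n_users=2000, seed=42))
meas = measure(panel)
table = estimation_table(panel, meas)
fits = linear_estimates(table)
```

printing the emotion effect from both estimators
(`examples/03_linear_iv.py`):

```
 OLS: emotion effect on dropout probability = +0.0160 (robust se 0.0088), n = 1009
TSLS: emotion effect on dropout probability = +0.0232 (robust se 0.0193), n = 1009
first-stage F = 210.3 (> 10 means a strong instrument)
```

Both estimators find that more positive language raises the probability
of dropping out; the 2SLS estimate is larger because the generator
plants a confounder that biases OLS toward zero, and the first-stage F
confirms the followee-mean instrument is strong. The survival side
(`examples/04_survival_iv.py`) completes the picture:

```
      iv    emotion: +0.00220/day  (95% CI +0.00141 to +0.00344)
      iv centrality: -0.00068/day  (95% CI -0.00180 to -0.00020)
```

positive emotion adds to the daily dropout hazard (shorter
participation) while a deeper position in the network core subtracts
from it (longer participation).

The `examples/` directory walks through every capability: simulation and
homophily testing (01), measurement and censoring (02), linear IV (03),
survival IV (04), hashtag-interest profiling (05), and estimator
recovery on ground-truth test beds (06). A thin CLI wraps the same
functions (`attrical run-all --seed 1 --out run/`).

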