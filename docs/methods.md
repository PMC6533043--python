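# Methods

## Study design being modelled

A cohort of community members is observed at two timestamps, obs1 and
obs2 (defaults 180 and 730 days after simulation start, i.e. a roughly
1.5-year follow-up). Independent variables and instruments are measured
from activity up to obs1; outcomes from activity between obs1 and obs2.
A user's binary dropout status is 1 when their last post is at or before
obs1 (strict ">" keeps the boundary explicit). Time is real-valued days
throughout; calendar dates are a presentation concern only.

## Measurement

**Emotion.** Each post is scored on the dual-scale lexicon convention:
positive term strengths live in [2, 5], negative in [−5, −2]; a tweet's
score is (max positive strength, default 1) + (min negative strength,
default −1), an integer in [−4, 4]. The aggregation of the two scales by
summation is a package choice — only the [−4, 4] output range is fixed
by the measurement contract — and the `Lexicon` is pluggable so a richer
scorer can be swapped in; the estimators, not the NLP, are the point.
Preprocessing removes @-mentions, #-hashtags and URLs, lower-cases and
whitespace-tokenises; "words" in the eligibility filter are these
tokens. A user's emotion is the mean score over original (non-retweet)
posts; users with more than 10 original tweets and more than 50 tokens
enter the measured sample.

**Network position.** In-coreness on the who-follows-whom digraph (edge
A→B when A follows B): the largest k such that the user belongs to a
subgraph in which every member has in-degree ≥ k. Computed via igraph's
k-core decomposition; a brute-force peeling oracle verifies it in the
test suite.

**Instruments.** Unweighted followee means of measured emotion and
centrality, in two modes: all followees, or single-way followees (those
not following back, which removes the user's reflected influence on the
instrument). Users with an empty (single-way) followee set are excluded
from the corresponding estimation sample.

**Covariates.** Social capital (followee/post/follower counts), activity
level (active days = creation to last first-window post; per-day rates),
observational bias (tweets and followees actually used in measurement),
and the alternative-channel controls: the proportion of instrument-set
followees active in the second window and their mean active duration.
These controls close the pathway by which followees' attributes could
affect the user's dropout through the followees' own attrition.

## Censoring

Identical interval censoring declares dropout when the silence before
obs2 strictly exceeds a fixed π; personalized censoring uses
λπ + (1−λ)·I_i, with I_i the user's mean inter-post interval over
first-window posts ((last − first)/(n − 1); fewer than two posts falls
back to π, flagged). Event times are last-post − obs1; censored users
carry the full obs2 − obs1 window. λ = 1 reduces bitwise to the
identical scheme. The (π, λ) tuner maximises agreement between statuses
predicted from first-window activity alone and observed second-window
statuses over a grid (defaults π ∈ {7, 14, 30, 60, 90, 180} days,
λ ∈ {0, 0.25, 0.5, 0.75, 1}), ties broken toward smaller π then larger
λ. The survival sample keeps users active past obs1.

## Estimators

**Linear probability.** OLS and 2SLS, both with HC1 sandwich covariance
(the variant choice among the HC family is the package's). The 2SLS
covariance evaluates structural residuals at the *original* endogenous
regressors and sandwiches with the projected ones — the proper 2SLS
variance, not the naive two-step one. The first-stage F is the robust
Wald statistic of the excluded instruments divided by their number, so
with one instrument it equals the squared robust t. The Wu-Hausman test
is the regression-based control-function form (first-stage residuals
appended to the structural equation, robust Wald on their coefficients,
F reference); the contrast form is exposed as an independent check.
Missing values are handled by listwise deletion with a logged count.
Centrality is excluded from the linear model by design: users who
dropped out long before obs1 would have their *later* network position
explaining *earlier* dropout. Cross-specification equality of the
emotion coefficient is tested by a paired user-level bootstrap
(refitting both specifications per replicate, which respects the
overlap of their samples); an analytic no-overlap variant is also
available, and is what the pipeline reports by default for speed.

**Survival.** Kaplan-Meier product-limit for description (median =
smallest t with S(t) ≤ 0.5, flagged undefined when never reached).
Aalen's additive hazards model estimates cumulative coefficients by
least-squares increments dB(t) = (X'X)⁻¹X'dN(t) over the at-risk set at
each event time, ties processed jointly. The reliable estimation window
ends at the first event time whose at-risk Gram matrix, diagonally
rescaled to correlation form so that covariate units cannot decide the
window, has condition number above 1e8. The IV extension regresses each
endogenous covariate on instruments plus exogenous covariates and adds
the residuals as ordinary covariates with time-varying effects (a
control-function construction); identically-zero residual columns are
dropped, since a perfect first stage leaves nothing to control. Both
emotion and centrality are endogenous in the survival models, with the
two followee means as joint instruments; their per-endogenous joint
first-stage F is recorded.

The reported "mean coefficient" is the least-squares slope of B_k(t) on
t over the reliable window — the time-averaged instantaneous effect per
day under a locally linear approximation, robust to early-time noise;
the terminal B_k(τ)/τ variant is also exposed. 95% intervals come from a
case (user-level) percentile bootstrap, 1000 replicates by default and
reducible for desk-scale runs, with the first stage re-run inside every
replicate; singular replicates are dropped and counted, with a warning
above 10%.

## Interests

Hashtag corpora per group (dropout states; emotion terciles with the
lower groups absorbing the remainder and ties broken by stable user-id
order). tf is the tag count in the group corpus; idf(t) = ln(1 + G/g_t)
over the G groups being compared, smoothed so a ubiquitous tag keeps a
small positive score; absent tags score 0 by contract. Similarity
between two groups is Spearman's ρ over the union vocabulary with
average ranks for ties; the p-value uses the large-sample t
approximation, with exact permutation enumeration available for union
vocabularies of at most 8 tags (full enumeration beyond that is
computationally unreasonable). Pairs without rank variation are
degenerate and flagged.

## Homophily

Newman's assortativity r on the directed mixing matrix (each directed
edge counted once, no symmetrisation). Significance comes from a
label-permutation null — the graph held fixed, labels shuffled
preserving counts, 1000 permutations by default — the minimal
exchangeability null; z = (r_obs − mean)/sd with a 0/0 → 0 convention
for degenerate nulls, and an add-one-smoothed two-sided p.

## The synthetic community generator

The generator emulates exactly the statistical structure the estimators
assume, with every causal arrow explicit:

- **Network.** Each user carries a latent binary group and a heavy-tailed
  lognormal *engagement* trait. Out-degree is Poisson with mean
  proportional to engagement (mean 12); targets are drawn by Gumbel
  top-k with weights combining same-group homophily (multiplier
  1 + homophily_strength) and engagement-assortative attachment
  (engaged users pull harder toward engaged targets). The assortative
  elite forms a nested dense core, giving the in-coreness centrality
  graded dispersion as in real follow networks, while homophily on the
  group plants label assortativity.
- **Emotions.** Two passes: a first-pass draw e0 = group shift +
  0.8·confounder + noise, then emotion = group shift + peer_weight ×
  (followee mean of e0) + 0.8·confounder + noise, clamped to [−4, 4].
  The peer term is the instrument-relevance channel; the shared group
  shift adds the homophily channel. The confounder is i.i.d. normal and
  never observed by the pipeline.
- **Dropout.** A per-user constant additive hazard h = b₀ + b_e·emotion
  + b_c·coreness + b_u·confounder (floored at 0 with a logged warning),
  giving an exponential dropout time from account creation; piecewise-
  constant hazards keep closed-form checks available. The binary outcome
  is generated jointly (dropout time < obs2) so linear and survival
  mechanisms agree; a separate linear-probability draw is available via
  `binary_mechanism="linear"`.
- **Exclusion by construction.** Followee attributes reach a user's
  outcome only through the user's own emotion (peer channel) and through
  followees' own dropout times (the alternative channel the covariates
  control) — never directly.
- **Posts.** Poisson streams at lognormal per-user rates from creation
  until min(dropout, obs2). Token lists are emitted from the synthetic
  lexicon so each post's sentiment score equals the user's true emotion
  plus rounding noise — the scorer is therefore exercised, not
  bypassed. A fixed fraction are retweets (excluded from measurement).
- **Hashtags.** Each post samples tags from an even mixture of the topic
  distribution of the user's emotion tercile and of their dropout
  status; by default the negative tercile shares its (disjoint-support)
  topic with nondropouts and the positive tercile with dropouts.

Default parameters (n = 2000 users, mean out-degree 12, peer weight 0.7,
confounder sd 1 with loading 0.8, hazard 0.010/day baseline,
+0.003/day per emotion unit, −0.0003/day per coreness unit, −0.004/day
per confounder unit, posting rate 0.2/day, observations at 180 and 730
days) are chosen for statistical power of the recovery and sign tests at
desk scale: effects are strong enough to be detected on a single panel
of 2000 users, attrition is fast enough (median lifetime a few months)
that both censored and uncensored outcomes are plentiful, and posting is
frequent enough that most surviving users pass the eligibility filter.
The confounder *attenuates* (loads with opposite signs on emotion and
the hazard), reproducing the qualitative situation in which ignoring
endogeneity underestimates the effect of interest.

What the generator does not emulate: real language (tokens are lexicon
draws, so sentiment measurement error is purely rounding noise, far
cleaner than real NLP error), platform dynamics (recommendation,
moderation, lurking without posting), multiple accounts per person, and
time-varying covariates or hazards. Passing tests therefore show that
the estimators recover what they claim *under the model's assumptions* —
not that those assumptions hold on any particular real community.

Two stripped-down test beds bypass the measurement layer for estimator
checks with known truth: `linear_iv_dataset` (y = 0.3·x₁ + u + ε,
x₁ = 0.6·z̄ + 0.8·u + ν with a network-built followee-mean instrument)
and `hazard_iv_dataset` (additive hazard 0.15 + 0.02·x₁ + 0.02·u per
day, scalar instrument, administrative censoring at 30 days).

## Numerical choices and degenerate inputs

- Peeling ties in the coreness oracle cannot affect the result; the
  production path delegates to igraph's round-based decomposition.
- Strict inequalities at every censoring boundary ("more than").
- Aalen increments use batch linear solves over the event-time grid; the
  scale-invariant condition cap (1e8) defines the reliable window, and
  estimation stops rather than regularises.
- Bootstrap intervals are percentile 2.5/97.5; seeds flow from a single
  root `SeedSequence`, so identical (config, seed) gives bit-identical
  panels and CIs.
- Degenerate inputs raise typed errors rather than returning silently:
  single-label assortativity, sub-3 tag unions or rank-flat profiles,
  fewer than two event times for a mean coefficient, empty tuning grids.

## Problem sizes used in the shipped checks

Recovery and calibration checks run at n = 2000 (linear, 200
replications), n = 1000 (diagnostics, 500 replications; survival
recovery, 100 replications), and n = 400 with 200 bootstrap replicates
over 200 panels for survival-IV interval coverage; the qualitative sign
pattern is checked on 50 panels of 2000 users. These sizes give the
Monte-Carlo error needed for the stated tolerances while keeping a full
run at desk scale.

## Known limitations

- The additive-hazard control function assumes additive, time-constant
  true effects; with strong effect heterogeneity the "mean coefficient"
  is a window-dependent summary, not a structural constant.
- The followee-mean instrument is only as good as the exclusion
  restriction; the package can measure relevance (F) and endogeneity
  (Wu-Hausman) but, as always, cannot test exclusion itself.
- In small samples the Aalen IV mean coefficient shows mild upward
  finite-sample bias (visible at n ≤ 1000 in the test beds, vanishing by
  n ≈ 4000); the bootstrap intervals reflect it, and coverage stays near
  nominal.
- The lexicon scorer is deliberately minimal (no negation, boosters or
  emoticons); swap in a richer `Lexicon`/scorer for real text.
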