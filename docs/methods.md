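# Methods

## Model

One latent state drives everything: the participant's practice history
— the ordered day indices on which dietary self-monitoring was actually
executed. From it the model computes, for each day *n* (1-based, whole
days, a 21-day default window):

**Base-level activation.** *B(n)* = ln Σᵢ tᵢ^(−dᵢ), summing over all
practices executed before day *n*, with tᵢ = *n* − (day of practice
*i*) ≥ 1 the practice's age at prediction time. Decay is per practice:
d₁ = a, and dᵢ = c·exp(m₍ᵢ₋₁₎) + a, where m₍ᵢ₋₁₎ is the activation of
the first *i*−1 practices evaluated at the encoding time of practice
*i*. This is the established two-parameter spacing-sensitive decay
rule: massed practice raises activation at encoding and hence speeds
forgetting of that practice. A constant-decay mode (dᵢ = d for all
*i*) is provided; it is mainly used to check against brute-force
direct-summation references, and the spacing rule degenerates to it
exactly when c = 0. Each practice keeps the decay assigned at
encoding, which depends only on earlier practices — so the per-practice
decays are a stable prefix as history grows, and base-level activation
for a fixed cohort can be precomputed once and reused for every
parameter vector during fitting (it does not involve the free
coefficients).

**Goal pursuit.** Total activation *A* = β₀ + β·*B*; retrieval
probability *P_G* = logistic((*A* − τ)/s); intention-action translation
*A′* = *Tr*·*A* (multiplicative by default; an additive variant
*A′* = *A* + *Tr* is a configuration switch) and success probability
*P_S* = logistic((*A′* − τ)/s).

**Habit formation.** The habitual rule's utility starts at *U₀* and
after each executed day moves towards the constant per-execution
reward *R₀* by the delta rule *U* ← *U* + α(*R₀* − *U*), taking effect
from the next day. Execution probability is a two-option Boltzmann
choice against a zero-utility do-nothing rule:
*P_H* = logistic(*U*/(√2·s_u)).

**Output.** *P* = *P_G·P_S* + (1 − *P_G*)·*P_H*; the two summands are
the goal and habit contribution curves. Prediction is strictly
autoregressive on the *observed* sequence: day *n* conditions on days
1..*n*−1 of the data, never on the model's own predictions.

**Empty-history convention.** Before the first observed execution the
power-law sum is empty (ln of it would be −∞), so the β·*B* term is
dropped and *A* = β₀; likewise *U* = *U₀*. Day 1 always falls under
this convention.

Spreading activation is not modelled separately; any contextual
contribution is absorbed into the intercept β₀.

## Parameters

Fixed architecture constants (`SystemParams`), all dimensionless
except τ (activation units): c = 0.217, a = 0.177 (decay control),
s = 0.25 (activation noise), s_u = 0.25 (utility noise), α = 0.2
(learning rate), τ = 0 (retrieval threshold). These are conventional
values from the spacing-effect and health-behaviour ACT-R modelling
literature; all are configurable, and every fit holds them fixed.

Free coefficients (`FreeParams`, five per study arm): β₀ (activation
units), β, *Tr* (dimensionless), *U₀*, *R₀* (utility units). None is
sign-constrained — fitted β is typically negative in this domain, which
gives the counter-intuitive but data-driven dynamic that heavily
practiced (high-*B*) histories *lower* total activation.

Built-in presets carry the published coefficient sets for three
intervention arms of a 21-day program — self-management
(β₀ = 1.3245, β = −0.6909, *Tr* = 1.8575, *U₀* = 0.1959, *R₀* = 0.7983,
n = 49), tailored feedback (3.2422, −1.6991, 3.6615, 1.9833, 1.9909,
n = 23) and intensive support (3.6510, −2.2174, 3.1929, −0.3126,
4.7796, n = 25).

## Synthetic cohorts

The generator runs the model forward: each day's success probability is
computed from the *simulated* history so far, an outcome is drawn
Bernoulli, and on adherent days 2–4 upload timestamps are emitted
uniformly within the day (non-adherent days carry a single entry with
probability `p_single_entry` = 0.2, so the ≥2-entries binarisation rule
is genuinely exercised; the value is a free choice — real logs contain
occasional single-photo days but no published per-day entry counts
exist). A configurable fraction of participants is forced all-zero to
exercise the exclusion filter. Per-participant RNG streams are keyed by
participant index under the master seed, so growing a cohort never
changes existing participants.

Because generation is self-consistent, parameter-recovery experiments
are meaningful: refitting a simulated cohort should reproduce the
generating model's *curve*. Two real-data features are deliberately
not emulated: between-participant heterogeneity (all participants in an
arm share one coefficient set; an outcome-noise hook
`noise_eps`/`noise_p` is the only misspecification device) and the
low, steeply declining adherence levels seen in field data. At the
built-in presets the self-consistent dynamics stabilise at high
adherence (group means ≈0.94–1.00 with a weak decline), because
coefficients estimated *conditionally* on observed declining histories
do not generatively reproduce those histories. Passing tests on these
cohorts therefore validate the machinery (accounting, fitting,
uncertainty quantification), not field-realistic adherence levels.

A consequence worth stating explicitly: on self-consistent cohorts the
habit-route contribution (1 − *P_G*)·*P_H* *grows* over the window
rather than fading. Early days have empty histories, so *A* = β₀ (large
and positive for all presets), *P_G* ≈ 1 and the habit weight
1 − *P_G* ≈ 0; as practice accumulates, *B* rises and (with β < 0)
*P_G* falls, handing weight to the habit route. A fading-habit pattern
would require early histories that suppress retrieval — which these
equation forms and constants cannot produce.

## Fitting

The objective is the mean (not sum) over the T days — day 1 included
under the empty-history convention — of the squared difference between
the observed daily proportion adherent and the per-day mean of the
participants' predicted probabilities. Optimisation is unconstrained
in all five coefficients: BFGS with central finite-difference gradients
(step 1e−6), 20 random starts drawn uniformly from β₀, β, *U₀* ∈ [−5, 5]
and *Tr*, *R₀* ∈ [0, 5], lowest final objective wins. Starts are drawn
sequentially from one seeded generator, so a run with more starts
nests a run with fewer. If no start reports convergence the fit raises
with per-start diagnostics rather than returning silently.

Identifiability: a single 21-point group curve does not pin down all
five coefficients. Near-saturated (flat, high) curves in particular can
be fit equally well through the goal route (large β₀) or the habit
route (large *U₀*), so recovered coefficient values — including signs —
are not guaranteed even when the recovered curve is essentially exact.
Recovery claims are therefore made at the level of the predicted curve.

## Evaluation

MSE, RMSE = √MSE, and R² = 1 − SS_res/SS_tot about the observed mean,
computed on the group curves. A constant observed curve makes R²
undefined; it is reported as NaN, never clipped to 0, and R² is
reported unclipped in general (negative values are meaningful).
Bootstrap: participants are resampled with replacement (1000
replicates, 90% percentile intervals by default); both curves are
recomputed per replicate while the fitted coefficients stay fixed — no
per-replicate refit by default, since per-participant predictions
depend only on each participant's own history and can be computed once
and row-resampled. Ljung-Box: Q = n(n+2)·Σ_{k≤L} ρ̂²_k/(n−k), p-value
from χ²(L); the default L = 20 on a 21-day residual series mirrors
common practice for short adherence series but is statistically
degenerate (L ≈ n) — a smaller L is preferable when the choice is free.
Zero-variance residual series raise instead of returning a meaningless
statistic.

## Numerical and design choices

* Time is whole days; ages are integers ≥ 1, so the power law is never
  singular. Practice ages are interpreted at prediction time (ages
  since each execution), not as intervals from the first execution —
  the latter would make t₁ = 0 and the power law singular.
* Reward is constant per execution (*R* = *R₀*); a per-day reward
  schedule would slot into the utility recursion without interface
  changes.
* Retention percentages round to nearest integer via floor(x + 0.5).
* Day boundaries follow the calendar date of the timestamp as recorded
  (no timezone conversion); `min_entries` (default 2) is a parameter,
  not a hard-coded constant.
* The Ljung-Box statistic is implemented directly from the portmanteau
  formula so the statsmodels implementation can serve as an
  *independent* cross-check in the test suite.
* Problem sizes in tests and the acceptance script (cohorts of 40–500
  for fitting, 2000 for trend checks, 1000 bootstrap replicates) were
  chosen as the smallest sizes at which the corresponding statistical
  claims are stable across seeds.

## Known limitations

* No per-participant (hierarchical) fitting: one coefficient set per
  arm, as in the originating study design.
* No sub-daily time resolution, no spreading activation, no symbolic
  production system — only the four subsymbolic computations.
* The generator's self-consistency means it cannot, at the built-in
  presets, reproduce field-typical adherence levels (see above); use
  the noise hook or custom coefficients for that.
* BFGS with 20 starts is a heuristic against multimodality, not a
  global-optimality guarantee.
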