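# goalhabit

Dynamic modelling of adherence to daily dietary self-monitoring in
digital weight-loss programs, built on the subsymbolic layer of the
ACT-R cognitive architecture.

Participants in app-based weight-loss interventions are asked to record
their diet every day; a day counts as adherent when at least two
dietary entries are uploaded. Adherence typically starts high and
decays. `goalhabit` models the probability that a participant executes
self-monitoring on the next day, conditioned on their observed practice
history, as the combination of two mechanisms:

* **Goal pursuit** — the monitoring goal is retrieved from declarative
  memory with probability *P<sub>G</sub>* and translated into action
  with probability *P<sub>S</sub>*. Retrieval follows a logistic in the
  goal chunk's total activation *A* = β₀ + β·*B*, where
  *B* = ln Σᵢ tᵢ^(−dᵢ) is the base-level activation of the practice
  history (tᵢ the age of the *i*-th practice, dᵢ a spacing-sensitive
  decay d₁ = a, dᵢ = c·exp(m₍ᵢ₋₁₎) + a). The intention-action
  coefficient *Tr* rescales the activation before the success logistic.
* **Habit formation** — when the goal is not retrieved, the practiced
  "record diet" production rule may fire automatically with probability
  *P<sub>H</sub>*, a Boltzmann choice driven by the rule's utility *U*,
  which moves towards the reward *R₀* by a delta rule *U ← U + α(R₀ −
  U)* after every execution.

The composite day-ahead success probability is

&nbsp;&nbsp;&nbsp;&nbsp;*P* = *P<sub>G</sub>·P<sub>S</sub>* + (1 − *P<sub>G</sub>*)·*P<sub>H</sub>*,

and the two summands are the per-mechanism contribution curves. The
five free coefficients (β₀, β, *Tr*, *U₀*, *R₀*) are estimated per
study arm by multi-start BFGS, minimising the mean squared discrepancy
between the observed group adherence curve (daily proportion adherent)
and the mean predicted probability. Evaluation reports MSE/RMSE/R² with
percentile-bootstrap confidence intervals and a Ljung-Box residual
autocorrelation test.

The package is aimed at computational behavioural scientists and
digital-health methodologists who want to decompose adherence dynamics
into deliberate and habitual components, run what-if simulations, or
benchmark fitting pipelines on synthetic cohorts. Because the original
system logs of such studies are rarely shared, a self-consistent
synthetic-cohort generator (the generative model equals the inferential
model) with built-in presets for three intervention arms
(self-management n=49, tailored feedback n=23, intensive support n=25,
21 days) makes the whole pipeline runnable from scratch.

## Worked example

```python
from goalhabit import (AdherenceModel, DecayConfig, SystemParams,
                       count_outcome_events, exclude_all_zero, mean_adherence)
from goalhabit.simulate import group_presets, simulate_group

system, decay = SystemParams(), DecayConfig()
cohort, logs = simulate_group(group_presets()["sm"], system, decay, seed=42)
cohort, report = exclude_all_zero(cohort)
print(count_outcome_events(cohort), mean_adherence(cohort).mean)

model = AdherenceModel(system=system, decay=decay, n_starts=20, random_state=0)
model.fit(cohort.matrix)
print(model.free_params_)
print(model.decompose(cohort.matrix).iloc[[0, 10, 20]])
```

Output (abridged):

```
1029 0.9464868721926428
FreeParams(beta0=1.9258, beta=-1.0778, tr=1.5098, u0=-4.7710, r0=3.2843)
 day  goal_contrib  habit_contrib   p_smdb
   1      0.999540   6.218537e-10 0.999540
  11      0.776146   1.596664e-01 0.935812
  21      0.730994   1.877902e-01 0.918784
```

The 49-participant, 21-day cohort carries 49 × 21 = 1029 outcome
events. The fitted model reproduces the simulated group curve with
RMSE ≈ 0.024 (90% bootstrap CI on resampled cohorts 0.029–0.052), and
the decomposition table shows the goal-pursuit route dominating
throughout while the habit route's contribution builds up as practice
accumulates. Note the fitted coefficients differ from the generating
ones even though the curve is matched closely: a single 21-point group
curve does not jointly identify all five coefficients (see
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
goalhabit simulate --preset sm --seed 1 --out-dir run
goalhabit fit --sequences run/sequences.csv --starts 20 --seed 1 --out run/fit.json
goalhabit evaluate --sequences run/sequences.csv --fit run/fit.json --out run/eval.json
goalhabit decompose --sequences run/sequences.csv --fit run/fit.json --out run/decomposition.csv
# or everything at once from a JSON config:
goalhabit pipeline --config config.json
```

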