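# habitsim

A firing-rate simulator of dual cortico-striatal learning: how the brain's
goal-directed and habit systems learn the same task at the same time, and
how habits win when the rules change.

`habitsim` is aimed at computational neuroscientists studying basal-ganglia
learning, behavioral flexibility, and the circuit basis of inflexible
behavior (e.g., in addiction research, where impaired prefrontal outcome
coding is a candidate mechanism).

## The model

Two cortico-basal-ganglia loops learn a two-alternative forced-choice task
concurrently:

- **Medial loop (goal-directed):** prefrontal cortex (PFC) →
  dorsomedial striatum (DMS).  Cortico-striatal weights follow the reward
  prediction error `SNc_DMS = R − ExpRew`, with
  `ExpRew ← α R + (1−α) ExpRew`, α = 0.15.
- **Lateral loop (habit):** premotor cortex (PMC) → dorsolateral striatum
  (DLS).  Weights follow a salience signal `SNc_DLS = RectExp`, the running
  average of |R| — so this loop learns how often an action is taken, not
  whether it pays.

Each loop has two action channels with direct (D1 → GPi), indirect
(D2 → GPe → STN → GPi) and, laterally, hyperdirect (PMC → STN) pathways.
Population rates follow

    τ dA/dt = σ(I) − A + N(t),     σ(I) = max(tanh I, 0)

Euler-integrated at dt = 0.15 ms with per-step uniform noise.
Winner-take-all cortical inhibition makes the end-trial PFC argmax the
selected *outcome* and the PMC argmax the selected *action*; reward depends
only on the action.  Weight updates are three-factor
(`Δw = ±λ · SNc · CTX · MSN − d(w − w₀)`, clipped at 0).

An ideal-observer analysis turns per-trial selection probabilities into a
hazard-corrected log-likelihood ratio
`y_n = log(P1/P2) + log[((1−h)e^{y} + h)/(h e^{y} + (1−h))]`, h = 1/201,
whose first zero-crossing is the behavioral *change point*.

The session battery: initial learning (action 1 pays 1), then — inheriting
the trained weights — reward devaluation (pays 0.2), reward reversal
(action 2 pays 1), punished outcome (action 1 costs 0.5), and the latter
two with impaired PFC outcome coding (10% of each channel's output
misrouted to its competitor).  See `docs/methods.md` for every numerical
convention.

## Worked example

Train an agent, reverse the reward rule, and ask when an ideal observer
detects the switch in each cortical compartment:

```python
import numpy as np
from habitsim import (ModelParameters, estimate_selection_probabilities,
                      initial_learning, loglik_ratio_series,
                      reward_reversal, run_branched_protocol)

params = ModelParameters()
ens = run_branched_protocol(n_agents=1, root_seed=7,
                            initial_spec=initial_learning(),
                            followup_specs=[reward_reversal().truncated(300)],
                            params=params)
init, rev = ens.logs[0]
print("final trained weights:", np.round(init.weights_series[-1], 3))

est = estimate_selection_probabilities(rev.weights_before_trials, params,
                                       n_reps=200, seed=1)
cp_outcome = loglik_ratio_series(est.outcome).changepoint_trial
cp_action = loglik_ratio_series(est.action).changepoint_trial
print("PFC (outcome) change point:", cp_outcome)
print("PMC (action) change point:", cp_action)
```

Output:

```
final trained weights: [1.012 0.992 0.994 1.004 1.076 1.007 0.964 0.996]
PFC (outcome) change point: 10
PMC (action) change point: 53
```

The trained weight vector shows the learned policy (order: PFC→D1,
PFC→D2, PMC→D1, PMC→D2, each for channels 1, 2).  After 200 rewarded
trials the goal-directed DMS weights sit close to baseline — the reward is
fully predicted, so the prediction error that sustains them has vanished —
but the DLS has accumulated the stimulus-response bias for action 1
(D1 1.076 vs D2 0.964), because its salience signal never vanishes.  After
the reversal, the goal-directed compartment abandons outcome 1 within ten
trials, yet the habit keeps the motor compartment on action 1 five times
longer — the signature competition between adaptive and automatized
control.

The same pipeline is scriptable from the shell:

```bash
habitsim simulate --agents 20 --seed 1 --out runs/battery
habitsim analyze --ensemble runs/battery --reps 200 --out runs/analysis
habitsim report --analysis runs/analysis
```

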