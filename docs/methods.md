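# Model and methods

## The network

`habitsim` simulates two cortico-basal-ganglia loops that learn a
two-alternative forced-choice task concurrently:

- **Medial partition (goal-directed):** prefrontal cortex (PFC) projecting
  to the dorsomedial striatum (DMS).  Plasticity here follows the reward
  prediction error (RPE), so the loop tracks *which outcome is worth
  selecting*.
- **Lateral partition (habit):** premotor cortex (PMC) projecting to the
  dorsolateral striatum (DLS).  Plasticity here follows a salience signal
  (a running average of |reward|), so the loop tracks *which action has
  been engaged often* — a frequency-based stimulus-response memory.

Each partition carries two channels (one per choice).  A channel routes
cortical input through D1 medium spiny neurons to the GPi (direct pathway,
GO), through D2 neurons to GPe → STN → GPi (indirect pathway, NOGO), and,
in the lateral partition only, from PMC straight to the STN (hyperdirect
pathway, channel-matched).  GPi inhibits the corresponding cortical
population; cross-channel cortical inhibition (weight 1.6) forces a
winner-take-all readout.  The PFC winner is the selected *outcome*; the PMC
winner — additionally excited by the channel-matched PFC rate (weight 0.1)
— is the selected *action*, and only the action determines reward.

Population rates follow `tau dA/dt = sigma(I) - A + N(t)` with
`sigma = max(tanh, 0)`, Euler-integrated at dt = 0.15 ms
(tau = 12.8 ms STN, 20 ms GPe, 15 ms otherwise).  All gains, drives and
fixed weights are the published constants of the model
(`ModelParameters` defaults).

## Plasticity

After each trial, with reward R:

- `SNc_DMS = R − ExpRew` (RPE), `ExpRew ← 0.15·R + 0.85·ExpRew`;
- `SNc_DLS = RectExp`, `RectExp ← 0.15·|R| + 0.85·RectExp` — identical to
  `ExpRew` while rewards are non-negative, but positive for punishment too;
- each of the eight plastic weights w gets
  `Δw = ±λ · SNc · CTX · MSN − d(w − w0)` with the end-trial pre- and
  postsynaptic rates as gain factors (sign + for D1, − for D2), both
  channels every trial, clipped at 0.  λ is 20× smaller in the DLS than in
  the DMS, and the decay d = 0.02 caps any steady-state weight deviation at
  `λ·SNc·CTX·MSN/d ≤ λ/d` (= 0.125 for the DLS direct pathway).

Both dopamine signals are read *before* the trace update (subscript-
consistent with the RPE definition).  The rectified expectation uses |R|;
a raw-R variant is available as `rectexp_use_abs=False` for sensitivity
checks.  The printed STN→GPi term is implemented with a sign switch; the
default (excitatory) is the configuration in which D2 activity disinhibits
GPi, which the model's indirect-pathway (NOGO) function requires.

## Trial duration: the goal/habit race

The trial length — how long the network integrates before the end-trial
readout — is not part of the published constant set, yet it is the single
number that controls the competition between partitions, because the two
loops run at different speeds: lateral striatal currents are strong
(g_PMC = 1) while medial ones are weak (g_PFC = 0.4).

- **Long windows (≳300 ms):** every loop reaches its winner-take-all
  steady state.  The race is decided early, when channel asymmetries are
  tiny, and the clean PFC→PMC input (≈0.09 current difference) always wins.
  The capped DLS weight bias (≤0.125) then expresses *no* action bias, no
  habit can resist reversal, and the PMC change point collapses onto the
  PFC one.
- **Short windows (≲150 ms):** the fast lateral loop locks its
  winner-take-all on the DLS bias before the slow medial loop separates,
  so habit resists the PFC — but initial acquisition weakens and
  goal-directed learning slows, because end-trial rates (the plasticity
  gain factors) are still small at readout.

The default `trial_duration = 200 ms` (1333 Euler steps) sits at the
crossover: initial learning succeeds (ensemble median final P(action 1)
≈ 0.97), a trained DLS holds the previously rewarded action for tens of
trials against a reversed PFC, and punished/reversal change-point lags
between PMC and PFC reproduce the published ordering.  The window is a
genuine model-identification choice, calibrated once against the published
ensemble change-point medians and then frozen; with it, medial (PFC)
change points run somewhat later than the published medians (the model's
outcome exploration sheds accumulated evidence more slowly) while lateral
(PMC) change points and all orderings agree.  Because the readout is
mid-transient, end-trial PFC rates do not always separate by a large
margin at this window; at a 600 ms window the separation exceeds 0.2 in
>95% of unbiased trials.

## Other numerical conventions

- **Initial condition:** all 24 rates reset to 0 at trial start; noise
  drives the transient.  Weights and reward traces persist across trials
  and (by inheritance) across sessions.
- **Noise:** N ~ U[0, 0.1], one fresh draw per population per step
  ("amplitude 0.1"); a centered variant U[−0.05, 0.05] is available
  (`noise_centered`).
- **dr_PMC:** the premotor drive is absent from the published constant
  table although its current equation contains one; it is set to 1.5,
  equal to the prefrontal drive (symmetric cortical excitability).
- **Tie-breaking:** equal end-trial rates (measure zero under noise) are
  resolved by a fair coin from the trial's RNG stream.
- **Seeding:** one root seed per ensemble; agent i uses child i of
  `SeedSequence(root)`, session k child k of the agent, trial j entry j of
  the session's `generate_state`.  Any trial is replayable in isolation,
  and reruns are bit-identical.  Both integration backends (compiled and
  NumPy reference) consume the same MT19937 stream and agree to round-off.

## Sessions and analysis

The canonical battery: initial learning (action 1 pays 1; 200 trials),
then, each inheriting the trained weights *and* reward trace from the end
of initial learning: devaluation (pays 0.2), reward reversal (action 2
pays 1), punished outcome (action 1 costs 0.5), and the last two with
impaired PFC coding — all 2000 trials.  Robustness presets expose reversal
feedback {0.2, 0.5, 1, 2} and punishment {−0.2, −0.5, −1, −2}.  Trace
inheritance is implied by the expected reward starting near 1 in follow-up
sessions; a reset remains available by passing a fresh `RewardTrace`.

**Impaired PFC (PFC†):** each PFC channel routes (1−mix) of its output to
its own targets and mix to the opposing ones (default mix = 0.1), applied
to the striatal input, the PMC input, and (mirrored) to the GPi→PFC
feedback; the plasticity presynaptic factor uses the same mixed rate.
mix = 0.5 makes the two effective signals identical, destroying all
channel information.

**Selection probabilities:** for trial n, the weights it ran under are
frozen and the trial is replayed `n_reps` times with fresh noise; P1 is
the Laplace-smoothed frequency (k+1)/(n_reps+2), keeping log-ratios
finite.  PFC-outcome and PMC-action series come from the same replays.

**Change point:** the hazard-corrected log-likelihood ratio
`y_n = log(P1/P2) + log[((1−h)e^{y_{n−1}} + h)/(h e^{y_{n−1}} + (1−h))]`
with h = 1/201 and y_0 = 0, evaluated via `logaddexp` (stable for |y| in
the hundreds).  The change point is the first trial with y ≤ 0 (sessions
analyzed here start biased toward channel 1; a symmetric detector is also
provided).  Note y saturates near log((1−h)/h) + log(P1/P2), so the
detector trails the behavioral switch by the few trials needed to shed
that evidence.

**Group statistics:** two-sided Mann-Whitney U (U counts pairs with the
first sample larger; tie-corrected normal approximation) with Bonferroni-
adjusted alpha: 0.05/4 for the four change-point comparisons, 0.05/7 for
the steady-state comparisons.

## What the simulations do and do not show

All data are generated by the model itself; there is no empirical input.
Ensemble statistics characterize the model's behavior, not rodent
behavior: passing tests show that the implemented circuit reproduces the
intended computational phenomena (concurrent goal-directed and habit
learning, habit persistence under reversal/devaluation/punishment, and
the cost of degraded outcome coding), not that the circuit is a validated
model of any particular animal's physiology.

## Problem sizes used by the test suite and acceptance script

Full-scale ensembles (100 agents × 2000-trial sessions × 1000-repeat
probability estimation) are the published protocol.  The package's own
studies use these sizes, chosen once:

- steady-state/devaluation ensemble: 100 agents, follow-up sessions
  truncated to 600 trials, 300 replays per final-trial estimate (the
  devaluation comparison in `scripts/acceptance.py` runs the full
  2000-trial session with 1000 replays);
- change-point ensemble: 16 agents, sessions truncated to 600 trials,
  30 replays per trial, P1 series grown in 100-trial blocks until 50
  trials past the detected change point.

Truncation is safe because every trace and weight relaxes with time
constants ≤ 1/d = 50 trials; replay counts trade only estimator variance
(SE ∝ n_reps^{−1/2}).

## Known limitations

- No explicit thalamus, no spiking dynamics, no cortical Hebbian
  plasticity, exactly two channels.
- Reward schedules are deterministic per action (no variable-ratio /
  variable-interval schedules).
- The identified trial window leaves the medial readout noisier than the
  published model's: medial change-point medians deviate from the
  published values (while their impaired-vs-control orderings hold), the
  punished-outcome PFC-vs-PMC steady-state gap nearly closes, and a small
  PMC>PFC difference appears in devaluation where the reference reports
  none.  Treat medial (PFC) magnitudes as qualitative; lateral (habit)
  quantities are the calibrated ones.
- Very strong punishment can produce "punished runs" (salience-driven
  re-selection of the punished action); the phenomenon is reproducible via
  `robustness_presets()` but carries no quantitative claims here.
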