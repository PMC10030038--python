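"""Behavioral sessions: trial loop, reward rules, and ensemble protocols.

A session is a fixed number of two-alternative forced-choice trials under
one reward rule (reward per action).  The canonical protocol trains every
agent on an initial-learning session (action #1 pays 1, 200 trials) and
then challenges it, inheriting weights and reward trace, with one of the
follow-up rules: devaluation (0.2), reward reversal (action #2 pays 1),
punished outcome (action #1 costs 0.5), and the latter two with impaired
PFC outcome coding ("PFC-dagger").  Follow-up sessions run 2000 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ModelParameters, NetworkState, PlasticWeights, run_trial
from .plasticity import RewardTrace, update_weights

__all__ = [
    "SessionSpec", "SessionLog", "EnsembleResult",
    "reward_for_action", "run_session", "run_protocol",
    "run_branched_protocol",
    "initial_learning", "devaluation", "reward_reversal", "punished_outcome",
    "reward_reversal_impaired", "punished_outcome_impaired",
    "default_protocol", "robustness_presets",
    "WEIGHT_COLUMNS", "LOG_COLUMNS",
]

SeedLike = Union[int, np.random.SeedSequence]

WEIGHT_COLUMNS = [
    "w_pfc_d1_1", "w_pfc_d1_2", "w_pfc_d2_1", "w_pfc_d2_2",
    "w_pmc_d1_1", "w_pmc_d1_2", "w_pmc_d2_1", "w_pmc_d2_2",
]
LOG_COLUMNS = (["trial", "outcome", "action", "reward",
                "exp_rew", "rect_exp", "snc_dms",
                "pfc1", "pfc2", "pmc1", "pmc2"] + WEIGHT_COLUMNS)


@dataclass(frozen=True)
class SessionSpec:
    """Reward rule for one session: feedback per action, length, impairment."""

    name: str
    reward_action1: float
    reward_action2: float
    n_trials: int
    impaired: bool = False

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")

    def truncated(self, n_trials: int) -> "SessionSpec":
        """Same rule with a shorter trial count (for scaled-down studies)."""
        return replace(self, n_trials=n_trials)


# canonical session definitions
def initial_learning() -> SessionSpec:
    return SessionSpec("initial_learning", 1.0, 0.0, 200)


def devaluation() -> SessionSpec:
    return SessionSpec("devaluation", 0.2, 0.0, 2000)


def reward_reversal() -> SessionSpec:
    return SessionSpec("reward_reversal", 0.0, 1.0, 2000)


def punished_outcome() -> SessionSpec:
    return SessionSpec("punished_outcome", -0.5, 0.0, 2000)


def reward_reversal_impaired() -> SessionSpec:
    return SessionSpec("reward_reversal_pfc_impaired", 0.0, 1.0, 2000,
                       impaired=True)


def punished_outcome_impaired() -> SessionSpec:
    return SessionSpec("punished_outcome_pfc_impaired", -0.5, 0.0, 2000,
                       impaired=True)


def default_protocol() -> List[SessionSpec]:
    """Initial learning followed by the five follow-up challenges."""
    return [initial_learning(), devaluation(), reward_reversal(),
            punished_outcome(), reward_reversal_impaired(),
            punished_outcome_impaired()]


def robustness_presets() -> dict:
    """Alternative feedback magnitudes probing robustness of the two rules."""
    out = {}
    for r in (0.2, 0.5, 1.0, 2.0):
        out[f"reward_reversal_{r:g}"] = SessionSpec(
            f"reward_reversal_{r:g}", 0.0, r, 2000)
    for r in (-0.2, -0.5, -1.0, -2.0):
        out[f"punished_outcome_{r:g}"] = SessionSpec(
            f"punished_outcome_{r:g}", r, 0.0, 2000)
    return out


@dataclass
class SessionLog:
    """Per-trial record of one session.

    ``table`` has one row per trial: selections (1/2), reward, the reward
    trace after the trial's update, the RPE of the trial, end-trial cortical
    rates, and the post-update snapshot of the eight plastic weights (the
    state trial j+1 runs under).
    """

    spec: SessionSpec
    seed_entropy: int
    initial_weights: np.ndarray  # (8,) weights in force for trial 1
    table: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.table)

    @property
    def weights_series(self) -> np.ndarray:
        """(n_trials, 8) post-update weight snapshots."""
        return self.table[WEIGHT_COLUMNS].to_numpy()

    @property
    def weights_before_trials(self) -> np.ndarray:
        """(n_trials, 8) weights each trial was actually run under."""
        post = self.weights_series
        return np.vstack([self.initial_weights[None, :], post[:-1]])

    @property
    def cortical_rates(self) -> np.ndarray:
        """(n_trials, 4) end-trial pfc1, pfc2, pmc1, pmc2."""
        return self.table[["pfc1", "pfc2", "pmc1", "pmc2"]].to_numpy()


@dataclass
class EnsembleResult:
    """Protocol output for an ensemble of agents (agent id = list index)."""

    root_seed: int
    params: ModelParameters
    specs: List[SessionSpec]
    logs: List[List[SessionLog]]  # [agent][session]

    @property
    def n_agents(self) -> int:
        return len(self.logs)

    def session_logs(self, name: str) -> List[SessionLog]:
        """All agents' logs for the session with the given name."""
        idx = [i for i, s in enumerate(self.specs) if s.name == name]
        if not idx:
            raise KeyError(f"no session named {name!r}")
        return [agent[idx[0]] for agent in self.logs]


def reward_for_action(spec: SessionSpec, action: int) -> float:
    """Feedback delivered for the selected action (1 or 2)."""
    if action == 1:
        return spec.reward_action1
    if action == 2:
        return spec.reward_action2
    raise ValueError(f"action must be 1 or 2, got {action}")


def _trial_seeds(seed: SeedLike, n: int) -> np.ndarray:
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    # mask to 31 bits so seeds stay valid for every generator flavor
    return (ss.generate_state(n, dtype=np.uint32) & np.uint32(0x7FFFFFFF))


def _entropy_of(seed: SeedLike) -> int:
    if isinstance(seed, np.random.SeedSequence):
        e = seed.entropy
        return int(e if not isinstance(e, (list, tuple)) else e[0])
    return int(seed)


def run_session(weights: PlasticWeights, trace: RewardTrace,
                spec: SessionSpec, params: ModelParameters,
                seed: SeedLike, backend: str = "numba"):
    """Execute one session; returns (SessionLog, final weights, final trace).

    The inherited ``weights`` and ``trace`` are not modified.  Trial j draws
    its noise from a child seed ``j`` of ``seed``, so any single trial can be
    replayed in isolation.  The slow ``backend="numpy"`` path composes the
    public per-trial operations and is used for cross-validation.
    """
    weights.validate()
    seeds = _trial_seeds(seed, spec.n_trials)

    if backend == "numba":
        from . import _kernels as K

        (outcomes, actions, rewards, exp_log, rect_log, snc_log, rates_log,
         w_log, exp_final, rect_final) = K.run_session(
            weights.as_vector().copy(), trace.expected_reward,
            trace.rectified_expectation, params.pack(),
            spec.reward_action1, spec.reward_action2, spec.impaired,
            params.n_steps, seeds)
        final_w = PlasticWeights.from_vector(w_log[-1])
        final_trace = RewardTrace(
            expected_reward=exp_final, rectified_expectation=rect_final,
            last_reward=rewards[-1], snc_dms=snc_log[-1],
            snc_dls=rect_log[-2] if spec.n_trials > 1
            else trace.rectified_expectation)
    elif backend == "numpy":
        w = weights.copy()
        tr = trace.copy()
        outcomes = np.empty(spec.n_trials, np.int64)
        actions = np.empty(spec.n_trials, np.int64)
        rewards = np.empty(spec.n_trials)
        exp_log = np.empty(spec.n_trials)
        rect_log = np.empty(spec.n_trials)
        snc_log = np.empty(spec.n_trials)
        rates_log = np.empty((spec.n_trials, 4))
        w_log = np.empty((spec.n_trials, 8))
        for j in range(spec.n_trials):
            res = run_trial(w, params, int(seeds[j]),
                            impaired=spec.impaired, backend="numpy")
            reward = reward_for_action(spec, res.action)
            tr.observe(reward, params)
            w = update_weights(w, tr, res.state, params,
                               impaired=spec.impaired)
            outcomes[j], actions[j] = res.outcome, res.action
            rewards[j] = reward
            exp_log[j] = tr.expected_reward
            rect_log[j] = tr.rectified_expectation
            snc_log[j] = tr.snc_dms
            rates_log[j, 0:2] = res.state.pfc
            rates_log[j, 2:4] = res.state.pmc
            w_log[j] = w.as_vector()
        final_w, final_trace = w, tr
    else:
        raise ValueError(f"unknown backend {backend!r}")

    table = pd.DataFrame(
        {"trial": np.arange(1, spec.n_trials + 1),
         "outcome": outcomes, "action": actions, "reward": rewards,
         "exp_rew": exp_log, "rect_exp": rect_log, "snc_dms": snc_log,
         "pfc1": rates_log[:, 0], "pfc2": rates_log[:, 1],
         "pmc1": rates_log[:, 2], "pmc2": rates_log[:, 3]})
    for k, col in enumerate(WEIGHT_COLUMNS):
        table[col] = w_log[:, k]
    log = SessionLog(spec=spec, seed_entropy=_entropy_of(seed),
                     initial_weights=weights.as_vector(), table=table)
    return log, final_w, final_trace


def run_protocol(n_agents: int, root_seed: int,
                 spec_sequence: Sequence[SessionSpec],
                 params: Optional[ModelParameters] = None,
                 backend: str = "numba") -> EnsembleResult:
    """Run an ordered session sequence for an ensemble of agents.

    Agent ``i`` derives its seeds from child ``i`` of
    ``SeedSequence(root_seed)``; session ``k`` of an agent uses child ``k``
    of the agent's sequence.  Each agent starts from unbiased weights
    (all equal to ``w0``) and a zero reward trace; state is inherited
    across the sequence, so follow-up sessions see the trained weights.
    """
    specs = list(spec_sequence)
    if not specs:
        raise ValueError("spec_sequence must contain at least one session")
    if params is None:
        params = ModelParameters()
    agent_seqs = np.random.SeedSequence(root_seed).spawn(n_agents)
    logs: List[List[SessionLog]] = []
    for i in range(n_agents):
        session_seqs = agent_seqs[i].spawn(len(specs))
        weights = PlasticWeights.initial(params.w0)
        trace = RewardTrace()
        agent_logs = []
        for k, spec in enumerate(specs):
            log, weights, trace = run_session(
                weights, trace, spec, params, session_seqs[k],
                backend=backend)
            agent_logs.append(log)
        logs.append(agent_logs)
    return EnsembleResult(root_seed=root_seed, params=params,
                          specs=specs, logs=logs)


def run_branched_protocol(n_agents: int, root_seed: int,
                          initial_spec: SessionSpec,
                          followup_specs: Sequence[SessionSpec],
                          params: Optional[ModelParameters] = None,
                          backend: str = "numba") -> EnsembleResult:
    """Train once, then branch every follow-up from the trained state.

    This is the canonical study design: each follow-up session inherits the
    weights and reward trace from the *end of the initial-learning session*
    (not from the previous follow-up).  Seeding matches :func:`run_protocol`
    run as ``[initial, followup_k]``: agent ``i`` uses child ``i`` of the
    root sequence, the initial session child 0 and follow-up ``k`` child
    ``1 + k`` of the agent's sequence (so the single-follow-up case is
    bit-identical to the chained run).
    """
    followups = list(followup_specs)
    if params is None:
        params = ModelParameters()
    agent_seqs = np.random.SeedSequence(root_seed).spawn(n_agents)
    logs: List[List[SessionLog]] = []
    for i in range(n_agents):
        session_seqs = agent_seqs[i].spawn(1 + len(followups))
        weights = PlasticWeights.initial(params.w0)
        trace = RewardTrace()
        init_log, trained_w, trained_tr = run_session(
            weights, trace, initial_spec, params, session_seqs[0],
            backend=backend)
        agent_logs = [init_log]
        for k, spec in enumerate(followups):
            log, _, _ = run_session(trained_w, trained_tr, spec, params,
                                    session_seqs[1 + k], backend=backend)
            agent_logs.append(log)
        logs.append(agent_logs)
    return EnsembleResult(root_seed=root_seed, params=params,
                          specs=[initial_spec] + followups, logs=logs)
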