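"""Between-trial dopamine signals and cortico-striatal weight updates.

The medial (DMS) compartment learns from the reward prediction error,
``SNc_DMS = R - ExpRew``, where ``ExpRew`` is an exponential moving average
of past rewards.  The lateral (DLS) compartment learns from a salience-like
signal, ``SNc_DLS = RectExp``, the matching moving average of ``|R|`` —
positive for rewarding *and* aversive feedback, so the DLS tracks how often
an action is engaged rather than whether it pays off.

Each of the eight plastic weights receives a three-factor update
(dopamine x presynaptic cortical rate x postsynaptic MSN rate) plus a decay
pulling it back to the rest value ``w0``; weights never go negative.  Both
channels update on every trial — selectivity comes entirely from the rate
factors, and the weights of rarely selected channels simply relax to ``w0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ModelParameters, PlasticWeights, effective_pfc

__all__ = [
    "RewardTrace",
    "reward_prediction_error",
    "update_expected_reward",
    "update_rectified_expectation",
    "update_weights",
]


@dataclass
class RewardTrace:
    """Running reward statistics carried across trials (and sessions).

    ``snc_dms``/``snc_dls`` hold the dopamine signals of the most recent
    trial; both are computed from the trace values *before* that trial's
    update.
    """

    expected_reward: float = 0.0
    rectified_expectation: float = 0.0
    last_reward: float = 0.0
    snc_dms: float = 0.0
    snc_dls: float = 0.0

    def copy(self) -> "RewardTrace":
        return RewardTrace(self.expected_reward, self.rectified_expectation,
                           self.last_reward, self.snc_dms, self.snc_dls)

    def observe(self, reward: float, params: ModelParameters) -> None:
        """Fold one trial's reward into the trace (pre-update RPE/salience)."""
        self.snc_dms = reward_prediction_error(reward, self.expected_reward)
        self.snc_dls = self.rectified_expectation
        self.expected_reward = update_expected_reward(
            self.expected_reward, reward, params.alpha)
        self.rectified_expectation = update_rectified_expectation(
            self.rectified_expectation, reward, params.alpha,
            use_abs=params.rectexp_use_abs)
        self.last_reward = reward


def reward_prediction_error(reward: float, exp_rew: float) -> float:
    """RPE: received minus expected reward (dopamine signal to the DMS)."""
    if not (math.isfinite(reward) and math.isfinite(exp_rew)):
        raise ValueError("reward and expectation must be finite")
    return reward - exp_rew


def update_expected_reward(exp_rew: float, reward: float, alpha: float
                           ) -> float:
    """Exponential moving average: alpha*R + (1-alpha)*ExpRew."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha * reward + (1.0 - alpha) * exp_rew


def update_rectified_expectation(rect_exp: float, reward: float, alpha: float,
                                 use_abs: bool = True) -> float:
    """Moving average of |R| (salience).

    For strictly non-negative reward histories with equal initialization this
    coincides exactly with the expected reward.  ``use_abs=False`` is a
    sensitivity variant that integrates the raw reward instead.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    r = abs(reward) if use_abs else reward
    return alpha * r + (1.0 - alpha) * rect_exp


def update_weights(weights: PlasticWeights, trace: RewardTrace,
                   end_state, params: ModelParameters,
                   impaired: bool = False) -> PlasticWeights:
    """Apply one trial's weight updates; returns a new PlasticWeights.

    ``end_state`` is the end-trial :class:`~habitsim.core.NetworkState`.
    DMS weights move with ``snc_dms`` (sign-reversed for D2), DLS weights
    with the non-negative ``snc_dls``, each gated by the end-trial pre- and
    postsynaptic rates and decayed toward ``w0``.  In impaired sessions the
    presynaptic PFC factor is the channel-mixed effective rate.  Any weight
    pushed below zero is reset to exactly zero.
    """
    p = params
    mix = p.mix if impaired else 0.0
    pfc = effective_pfc(end_state.pfc, mix)
    pmc = np.asarray(end_state.pmc, dtype=float)

    new = weights.copy()
    new.pfc_d1 += (p.lambda_dms_d1 * trace.snc_dms * pfc * end_state.d1[0]
                   - p.d * (weights.pfc_d1 - p.w0))
    new.pfc_d2 += (-p.lambda_dms_d2 * trace.snc_dms * pfc * end_state.d2[0]
                   - p.d * (weights.pfc_d2 - p.w0))
    new.pmc_d1 += (p.lambda_dls_d1 * trace.snc_dls * pmc * end_state.d1[1]
                   - p.d * (weights.pmc_d1 - p.w0))
    new.pmc_d2 += (-p.lambda_dls_d2 * trace.snc_dls * pmc * end_state.d2[1]
                   - p.d * (weights.pmc_d2 - p.w0))
    for arr in (new.pfc_d1, new.pfc_d2, new.pmc_d1, new.pmc_d2):
        np.maximum(arr, 0.0, out=arr)
    return new
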