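"""Ideal-observer change-point detection and ensemble performance statistics.

Per-trial selection probabilities are estimated by freezing the plastic
weights a trial was run under and replaying that trial many times with
fresh noise.  The resulting P1 series feeds a normative evidence
accumulator: the log-likelihood ratio

    y_n = log(P1_n / P2_n)
          + log(((1 - h) exp(y_{n-1}) + h) / (h exp(y_{n-1}) + (1 - h)))

whose hazard term h discounts old evidence at the a-priori rate of rule
switches.  In a session that starts biased toward channel 1, the first
non-positive y marks the trial at which an ideal observer concludes the
agent's preference has flipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import ModelParameters

__all__ = [
    "SelectionProbabilitySeries", "SelectionEstimate", "ChangePointResult",
    "GroupComparison", "estimate_selection_probabilities",
    "loglik_ratio_series", "detect_changepoint",
    "steady_state_performance", "compare_groups",
]


@dataclass
class SelectionProbabilitySeries:
    """Smoothed per-trial probability of selecting channel 1.

    Laplace smoothing with ``pseudocount`` per channel keeps P1 strictly
    inside (0, 1): P1 = (k + c) / (n_reps + 2c) for k channel-1 picks.
    """

    p1: np.ndarray
    n_reps: int
    pseudocount: float = 1.0

    def __post_init__(self):
        self.p1 = np.asarray(self.p1, dtype=float)
        if np.any(self.p1 <= 0.0) or np.any(self.p1 >= 1.0):
            raise ValueError("smoothed P1 must lie strictly in (0, 1)")

    @property
    def p2(self) -> np.ndarray:
        return 1.0 - self.p1

    def __len__(self) -> int:
        return len(self.p1)


class SelectionEstimate(NamedTuple):
    """P1 series for PFC outcome selection and PMC action selection."""

    outcome: SelectionProbabilitySeries
    action: SelectionProbabilitySeries


@dataclass
class ChangePointResult:
    """Log-likelihood-ratio series and the detected change-point trial."""

    y: np.ndarray
    hazard: float
    changepoint_trial: Optional[int]  # 1-based; None if no crossing


@dataclass
class GroupComparison:
    u: float
    p_value: float
    adjusted_alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.adjusted_alpha


def _smooth(counts: np.ndarray, n_reps: int, pseudocount: float) -> np.ndarray:
    return (counts + pseudocount) / (n_reps + 2.0 * pseudocount)


def estimate_selection_probabilities(
        weights_per_trial: np.ndarray, params: ModelParameters,
        n_reps: int, seed: Union[int, np.random.SeedSequence],
        impaired: bool = False, pseudocount: float = 1.0
) -> SelectionEstimate:
    """Estimate P1 per trial by replaying each trial's weights ``n_reps`` times.

    ``weights_per_trial`` is (n_trials, 8) — typically
    ``SessionLog.weights_before_trials``, the weights each trial actually ran
    under.  Both cortical readouts are counted from the same replays: the
    PFC outcome series and the PMC action series.  Replay r of trial j uses
    a seed drawn deterministically from ``seed``, independent of the session
    noise.
    """
    w = np.ascontiguousarray(weights_per_trial, dtype=float)
    if w.ndim != 2 or w.shape[1] != 8 or w.shape[0] == 0:
        raise ValueError("weights_per_trial must be non-empty (n_trials, 8)")
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rep_seeds = (ss.generate_state(w.shape[0] * n_reps, dtype=np.uint32)
                 .reshape(w.shape[0], n_reps) & np.uint32(0x7FFFFFFF))

    from . import _kernels as K

    counts = K.count_selections(w, params.pack(), impaired,
                                params.n_steps, rep_seeds)
    return SelectionEstimate(
        outcome=SelectionProbabilitySeries(
            _smooth(counts[:, 0], n_reps, pseudocount), n_reps, pseudocount),
        action=SelectionProbabilitySeries(
            _smooth(counts[:, 1], n_reps, pseudocount), n_reps, pseudocount))


def loglik_ratio_series(probs: SelectionProbabilitySeries,
                        hazard: Optional[float] = None) -> ChangePointResult:
    """Hazard-corrected log-likelihood ratio of the P1 series.

    Starts from y_0 = 0 (the hazard correction vanishes there, so
    y_1 = log(P1/P2) of the first trial).  Evaluated with ``logaddexp`` so
    the recursion is stable for |y| in the hundreds.  The change point is
    detected with the default start-toward-channel-1 orientation.
    """
    h = 1.0 / 201.0 if hazard is None else float(hazard)
    if not 0.0 < h < 1.0:
        raise ValueError(f"hazard must lie in (0, 1), got {h}")
    p1 = probs.p1
    if np.any(p1 <= 0.0) or np.any(p1 >= 1.0):
        raise ValueError("P1 must lie strictly in (0, 1)")
    log_lr = np.log(p1) - np.log1p(-p1)
    y = np.empty(len(p1))
    y_prev = 0.0
    log_h = np.log(h)
    log_1mh = np.log1p(-h)
    for n in range(len(p1)):
        correction = (np.logaddexp(log_1mh + y_prev, log_h)
                      - np.logaddexp(log_h + y_prev, log_1mh))
        y_prev = log_lr[n] + correction
        y[n] = y_prev
    result = ChangePointResult(y=y, hazard=h, changepoint_trial=None)
    result.changepoint_trial = detect_changepoint(result)
    return result


def detect_changepoint(result: ChangePointResult,
                       orientation: str = "one_to_two") -> Optional[int]:
    """First zero-crossing of the log-likelihood ratio (1-based trial).

    ``"one_to_two"`` assumes the session starts biased toward channel 1 and
    reports the first trial with y <= 0.  ``"symmetric"`` reports the first
    trial whose sign opposes the first nonzero y (or hits zero exactly).
    Returns None if no crossing occurs.
    """
    y = result.y
    if orientation == "one_to_two":
        hits = np.nonzero(y <= 0.0)[0]
        return int(hits[0]) + 1 if hits.size else None
    if orientation != "symmetric":
        raise ValueError(f"unknown orientation {orientation!r}")
    nonzero = np.nonzero(y != 0.0)[0]
    if nonzero.size == 0:
        return 1  # identically zero: crossed at once
    first_sign = np.sign(y[nonzero[0]])
    hits = np.nonzero((np.sign(y) == -first_sign) | (y == 0.0))[0]
    return int(hits[0]) + 1 if hits.size else None


def steady_state_performance(probs: SelectionProbabilitySeries) -> float:
    """Final-trial P1: the agent's end-of-session selection performance."""
    if len(probs) == 0:
        raise ValueError("empty probability series")
    return float(probs.p1[-1])


def compare_groups(a: Sequence[float], b: Sequence[float],
                   n_comparisons: int = 1) -> GroupComparison:
    """Two-sided Mann-Whitney U test with Bonferroni-adjusted alpha.

    The U statistic counts pairs where a sample from ``a`` exceeds one from
    ``b`` (ties count one half), i.e. complete separation with a above b
    yields U = len(a) * len(b).  The p-value uses the tie-corrected normal
    approximation, matching standard practice for ensembles of ~100 agents.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be at least 1")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return GroupComparison(u=float(res.statistic), p_value=float(res.pvalue),
                           adjusted_alpha=0.05 / n_comparisons)
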