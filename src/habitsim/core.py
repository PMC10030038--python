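"""Firing-rate dynamics of the two-partition cortico-basal-ganglia network.

The network contains a medial partition (prefrontal cortex -> dorsomedial
striatum, "goal-directed" loop) and a lateral partition (premotor cortex ->
dorsolateral striatum, "habit" loop).  Each partition holds two competing
channels, one per behavioral choice, and each channel routes cortical input
through the direct (striatum -> GPi), indirect (striatum -> GPe -> STN -> GPi)
and, in the lateral partition, hyperdirect (cortex -> STN) pathways.  Mutual
inhibition between the two cortical populations of a partition forces a
winner-take-all readout at the end of every trial: the PFC winner is the
selected *outcome*, the PMC winner the selected *action*.

Every population is described by its instantaneous firing rate ``A`` obeying

    tau * dA/dt = sigma(I) - A + N(t)

with ``sigma`` a rectified tanh, ``I`` the summed synaptic current and ``N``
a per-step uniform noise term.  Integration is explicit Euler.

Two integration backends are provided: a plain-NumPy reference path (this
module) and a compiled path (:mod:`habitsim._kernels`).  Both consume the
same MT19937 noise stream, so trajectories agree to floating-point
round-off (~1e-15 over a trial) and selections coincide for a given seed.
Reruns of either backend are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParameters",
    "NetworkState",
    "PlasticWeights",
    "TrialResult",
    "activation",
    "effective_pfc",
    "compute_currents",
    "euler_step",
    "run_trial",
]

# Internal channel indices are 0-based; the public selection API reports
# choices as 1 or 2, matching the task description ("action #1", "action #2").
MEDIAL, LATERAL = 0, 1  # partition indices (DMS / DLS)


@dataclass
class ModelParameters:
    """All fixed constants of the model.

    Defaults are the published parameter set of the model: synaptic weights,
    gains and drives of the network, the plasticity constants, and the
    change-point hazard.  Quantities the source model leaves open are
    documented package choices (see docs/methods.md): the noise support,
    ``dr_pmc``, and above all ``trial_duration`` — the integration window
    sets the balance of the goal-directed vs. habit race, and the 200 ms
    default is calibrated so a trained lateral (DLS) bias can hold the
    previously rewarded action against a reversed medial (PFC) preference.
    """

    # time constants (ms) and integration step
    tau_stn: float = 12.8
    tau_gpe: float = 20.0
    tau_default: float = 15.0
    dt: float = 0.15
    trial_duration: float = 200.0

    # noise: N ~ U[0, amplitude], or U[-amplitude/2, amplitude/2] if centered
    noise_amplitude: float = 0.1
    noise_centered: bool = False

    # cortical input gains
    g_pfc: float = 0.4
    g_pmc: float = 1.0

    # constant drives
    dr_gpe: float = 1.6
    dr_stn: float = 0.8
    dr_gpi: float = 0.2
    dr_pfc: float = 1.5
    dr_pmc: float = 1.5  # not in the published table; set equal to dr_pfc

    # fixed synaptic weights
    w_d2_gpe: float = 2.0
    w_stn_gpe: float = 0.4
    w_gpe_stn: float = 1.0
    w_hd: float = 0.3
    w_d1_gpi: float = 1.4
    w_stn_gpi: float = 1.6
    w_gpi_pfc: float = 1.8
    w_pfc_pfc: float = 1.6
    w_pfc_pmc: float = 0.1
    w_gpi_pmc: float = 1.8
    w_pmc_pmc: float = 1.6

    # plasticity
    lambda_dms_d1: float = 0.05
    lambda_dms_d2: float = 0.025
    lambda_dls_d1: float = 0.0025
    lambda_dls_d2: float = 0.00125
    d: float = 0.02
    w0: float = 1.0
    alpha: float = 0.15

    # analysis / impairment
    hazard: float = 1.0 / 201.0
    mix: float = 0.1  # PFC misrouting fraction applied in impaired sessions

    # resolution of stated ambiguities (see docs/methods.md)
    stn_gpi_excitatory: bool = True
    rectexp_use_abs: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("tau_stn", "tau_gpe", "tau_default", "dt", "trial_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dt >= min(self.tau_stn, self.tau_gpe, self.tau_default):
            raise ValueError("dt must be smaller than every time constant")
        for name in ("lambda_dms_d1", "lambda_dms_d2", "lambda_dls_d1",
                     "lambda_dls_d2", "d", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.mix <= 0.5:
            raise ValueError(f"mix must lie in [0, 0.5], got {self.mix}")
        if not 0.0 < self.hazard < 1.0:
            raise ValueError(f"hazard must lie in (0, 1), got {self.hazard}")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")

    @property
    def n_steps(self) -> int:
        """Euler steps per trial."""
        return int(round(self.trial_duration / self.dt))

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def pack(self) -> np.ndarray:
        """Flatten into the float64 vector consumed by the compiled kernels."""
        from . import _kernels as K

        pv = np.empty(K.N_PARAMS, dtype=np.float64)
        pv[K.P_TAU_STN] = self.tau_stn
        pv[K.P_TAU_GPE] = self.tau_gpe
        pv[K.P_TAU_DEFAULT] = self.tau_default
        pv[K.P_DT] = self.dt
        pv[K.P_NOISE_AMP] = self.noise_amplitude
        pv[K.P_NOISE_CENTERED] = 1.0 if self.noise_centered else 0.0
        pv[K.P_G_PFC] = self.g_pfc
        pv[K.P_G_PMC] = self.g_pmc
        pv[K.P_DR_GPE] = self.dr_gpe
        pv[K.P_DR_STN] = self.dr_stn
        pv[K.P_DR_GPI] = self.dr_gpi
        pv[K.P_DR_PFC] = self.dr_pfc
        pv[K.P_DR_PMC] = self.dr_pmc
        pv[K.P_W_D2_GPE] = self.w_d2_gpe
        pv[K.P_W_STN_GPE] = self.w_stn_gpe
        pv[K.P_W_GPE_STN] = self.w_gpe_stn
        pv[K.P_W_HD] = self.w_hd
        pv[K.P_W_D1_GPI] = self.w_d1_gpi
        # sign convention folded into the coefficient
        pv[K.P_W_STN_GPI] = (self.w_stn_gpi if self.stn_gpi_excitatory
                             else -self.w_stn_gpi)
        pv[K.P_W_GPI_PFC] = self.w_gpi_pfc
        pv[K.P_W_PFC_PFC] = self.w_pfc_pfc
        pv[K.P_W_PFC_PMC] = self.w_pfc_pmc
        pv[K.P_W_GPI_PMC] = self.w_gpi_pmc
        pv[K.P_W_PMC_PMC] = self.w_pmc_pmc
        pv[K.P_LAM_DMS_D1] = self.lambda_dms_d1
        pv[K.P_LAM_DMS_D2] = self.lambda_dms_d2
        pv[K.P_LAM_DLS_D1] = self.lambda_dls_d1
        pv[K.P_LAM_DLS_D2] = self.lambda_dls_d2
        pv[K.P_DECAY] = self.d
        pv[K.P_W0] = self.w0
        pv[K.P_ALPHA] = self.alpha
        pv[K.P_MIX] = self.mix
        pv[K.P_RECT_ABS] = 1.0 if self.rectexp_use_abs else 0.0
        return pv


@dataclass
class NetworkState:
    """Instantaneous firing rates of all 24 populations.

    Basal-ganglia arrays are indexed ``[partition, channel]`` with partition
    0 = medial (DMS loop) and 1 = lateral (DLS loop).  The same container is
    reused for per-population input currents, which share the layout.
    """

    d1: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    d2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    gpe: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    stn: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    gpi: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    pfc: np.ndarray = field(default_factory=lambda: np.zeros(2))
    pmc: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def as_vector(self) -> np.ndarray:
        """Canonical 24-vector: d1, d2, gpe, stn, gpi (row-major), pfc, pmc."""
        return np.concatenate([
            self.d1.ravel(), self.d2.ravel(), self.gpe.ravel(),
            self.stn.ravel(), self.gpi.ravel(), self.pfc, self.pmc,
        ])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "NetworkState":
        v = np.asarray(v, dtype=float)
        if v.shape != (24,):
            raise ValueError("state vector must have 24 entries")
        return cls(
            d1=v[0:4].reshape(2, 2).copy(), d2=v[4:8].reshape(2, 2).copy(),
            gpe=v[8:12].reshape(2, 2).copy(), stn=v[12:16].reshape(2, 2).copy(),
            gpi=v[16:20].reshape(2, 2).copy(),
            pfc=v[20:22].copy(), pmc=v[22:24].copy(),
        )


@dataclass
class PlasticWeights:
    """The four plastic cortico-striatal weight families, one value per channel.

    ``pfc_d1``/``pfc_d2`` live in the DMS (indexed by outcome channel),
    ``pmc_d1``/``pmc_d2`` in the DLS (indexed by action channel).  All are
    clipped at zero after every update.
    """

    pfc_d1: np.ndarray
    pfc_d2: np.ndarray
    pmc_d1: np.ndarray
    pmc_d2: np.ndarray

    @classmethod
    def initial(cls, w0: float = 1.0) -> "PlasticWeights":
        """Unbiased starting point: all eight weights equal the rest value."""
        return cls(*(np.full(2, float(w0)) for _ in range(4)))

    def as_vector(self) -> np.ndarray:
        """Flat order: pfc_d1[1,2], pfc_d2[1,2], pmc_d1[1,2], pmc_d2[1,2]."""
        return np.concatenate([self.pfc_d1, self.pfc_d2,
                               self.pmc_d1, self.pmc_d2]).astype(float)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "PlasticWeights":
        v = np.asarray(v, dtype=float)
        if v.shape != (8,):
            raise ValueError("weight vector must have 8 entries")
        return cls(v[0:2].copy(), v[2:4].copy(), v[4:6].copy(), v[6:8].copy())

    def copy(self) -> "PlasticWeights":
        return PlasticWeights(self.pfc_d1.copy(), self.pfc_d2.copy(),
                              self.pmc_d1.copy(), self.pmc_d2.copy())

    def validate(self) -> None:
        for name in ("pfc_d1", "pfc_d2", "pmc_d1", "pmc_d2"):
            arr = getattr(self, name)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass
class TrialResult:
    """End-of-trial snapshot: final rates plus the two winner-take-all picks."""

    state: NetworkState
    outcome: int  # PFC winner, 1 or 2
    action: int   # PMC winner, 1 or 2


def activation(current):
    """Rectified-tanh activation: 0 for non-positive input, tanh otherwise."""
    arr = np.asarray(current, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("activation input must be finite")
    out = np.where(arr > 0, np.tanh(np.maximum(arr, 0.0)), 0.0)
    if np.isscalar(current) or arr.ndim == 0:
        return float(out)
    return out


def effective_pfc(pfc_rates, mix: float):
    """Mix each PFC channel with its competitor: (1-mix)*own + mix*other.

    ``mix = 0`` is the identity (control); ``mix = 0.1`` is the impaired
    condition in which 10% of each outcome representation is misrouted to
    the opposing channel.  The sum of the two rates is preserved exactly.
    """
    if not 0.0 <= mix <= 0.5:
        raise ValueError(f"mix must lie in [0, 0.5], got {mix}")
    r = np.asarray(pfc_rates, dtype=float)
    if r.shape != (2,):
        raise ValueError("pfc_rates must be a pair")
    return np.array([(1.0 - mix) * r[0] + mix * r[1],
                     (1.0 - mix) * r[1] + mix * r[0]])


def compute_currents(state: NetworkState, weights: PlasticWeights,
                     params: ModelParameters, impaired: bool = False
                     ) -> NetworkState:
    """Per-population synaptic currents given the instantaneous rates.

    Returns a :class:`NetworkState` whose fields hold currents, not rates.
    In the impaired condition the cortical rates entering the striatum and
    PMC, and the pallidal feedback entering PFC, are channel-mixed by
    ``params.mix``.
    """
    p = params
    mix = p.mix if impaired else 0.0
    pfc_eff = effective_pfc(state.pfc, mix)
    cur = NetworkState()

    # striatum: cortex -> D1/D2 MSNs, gated by plastic weights
    cur.d1[MEDIAL] = p.g_pfc * weights.pfc_d1 * pfc_eff
    cur.d2[MEDIAL] = p.g_pfc * weights.pfc_d2 * pfc_eff
    cur.d1[LATERAL] = p.g_pmc * weights.pmc_d1 * state.pmc
    cur.d2[LATERAL] = p.g_pmc * weights.pmc_d2 * state.pmc

    # indirect pathway
    cur.gpe[:] = p.dr_gpe - p.w_d2_gpe * state.d2 + p.w_stn_gpe * state.stn
    cur.stn[:] = p.dr_stn - p.w_gpe_stn * state.gpe
    cur.stn[LATERAL] += p.w_hd * state.pmc  # hyperdirect, channel-matched

    # output node
    s = p.w_stn_gpi if p.stn_gpi_excitatory else -p.w_stn_gpi
    cur.gpi[:] = p.dr_gpi - p.w_d1_gpi * state.d1 + s * state.stn

    # cortex: winner-take-all mutual inhibition plus pallidal feedback
    gpi_fb = effective_pfc(state.gpi[MEDIAL], mix)  # same mixing rule
    other = np.array([state.pfc[1], state.pfc[0]])
    cur.pfc[:] = p.dr_pfc - p.w_gpi_pfc * gpi_fb - p.w_pfc_pfc * other
    other_m = np.array([state.pmc[1], state.pmc[0]])
    cur.pmc[:] = (p.dr_pmc + p.w_pfc_pmc * pfc_eff
                  - p.w_gpi_pmc * state.gpi[LATERAL] - p.w_pmc_pmc * other_m)
    return cur


def _tau_vector(params: ModelParameters) -> np.ndarray:
    """Per-population time constants in canonical 24-vector order."""
    tau = np.full(24, params.tau_default)
    tau[8:12] = params.tau_gpe   # GPe block
    tau[12:16] = params.tau_stn  # STN block
    return tau


def euler_step(state: NetworkState, currents: NetworkState,
               noise: np.ndarray, params: ModelParameters) -> NetworkState:
    """One explicit Euler step: A += (dt/tau) * (sigma(I) - A + N)."""
    a = state.as_vector()
    i = currents.as_vector()
    n = np.asarray(noise, dtype=float)
    if n.shape != (24,):
        raise ValueError("noise must have 24 entries")
    tau = _tau_vector(params)
    a_new = a + (params.dt / tau) * (activation(i) - a + n)
    return NetworkState.from_vector(a_new)


def _draw_noise(rs: np.random.RandomState, params: ModelParameters
                ) -> np.ndarray:
    if params.noise_centered:
        half = 0.5 * params.noise_amplitude
        return rs.uniform(-half, half, 24)
    return rs.uniform(0.0, params.noise_amplitude, 24)


def _select(rates: np.ndarray, rs: np.random.RandomState) -> int:
    """Winner-take-all readout with a random tie-break (1-based channel)."""
    if rates[0] > rates[1]:
        return 1
    if rates[1] > rates[0]:
        return 2
    return 1 if rs.uniform(0.0, 1.0) < 0.5 else 2


def run_trial(weights: PlasticWeights, params: ModelParameters, seed: int,
              impaired: bool = False, backend: str = "numba") -> TrialResult:
    """Integrate one trial from rest and read out the two selections.

    All rates start at zero; noise drives the transient and the mutual
    cortical inhibition separates the channels.  The trial is deterministic
    given ``seed``: both backends consume the identical MT19937 stream
    (24 uniform noise draws per step, in canonical state order, plus one
    extra draw only in the measure-zero event of a tie), so trajectories
    agree to round-off and selections coincide across backends.
    """
    weights.validate()
    if backend == "numba":
        from . import _kernels as K

        state24, outcome, action = K.trial(
            weights.as_vector(), params.pack(), impaired,
            params.n_steps, np.uint32(seed))
        return TrialResult(NetworkState.from_vector(state24),
                           int(outcome), int(action))
    if backend != "numpy":
        raise ValueError(f"unknown backend {backend!r}")

    rs = np.random.RandomState(np.uint32(seed))
    state = NetworkState()
    for step in range(params.n_steps):
        currents = compute_currents(state, weights, params, impaired)
        noise = _draw_noise(rs, params)
        state = euler_step(state, currents, noise, params)
        vec = state.as_vector()
        if not np.all(np.isfinite(vec)):
            bad = int(np.argmin(np.isfinite(vec)))
            raise FloatingPointError(
                f"non-finite rate at step {step}, state index {bad}")
    outcome = _select(state.pfc, rs)
    action = _select(state.pmc, rs)
    return TrialResult(state, outcome, action)
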