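"""Compiled integration kernels.

These numba kernels mirror the reference path in :mod:`habitsim.core`
exactly: same Euler update, same canonical state ordering, and the same
MT19937 noise stream (24 uniform draws per step, one extra draw only on a
selection tie), so a trajectory is bit-identical across backends for a
given seed.

Canonical 24-vector layout (partition m = medial/DMS, l = lateral/DLS):
    0-3   D1  [m ch1, m ch2, l ch1, l ch2]
    4-7   D2
    8-11  GPe
    12-15 STN
    16-19 GPi
    20-21 PFC [ch1, ch2]
    22-23 PMC [ch1, ch2]
"""

import math

import numpy as np
from numba import njit

# parameter-vector layout (shared with ModelParameters.pack)
P_TAU_STN = 0
P_TAU_GPE = 1
P_TAU_DEFAULT = 2
P_DT = 3
P_NOISE_AMP = 4
P_NOISE_CENTERED = 5
P_G_PFC = 6
P_G_PMC = 7
P_DR_GPE = 8
P_DR_STN = 9
P_DR_GPI = 10
P_DR_PFC = 11
P_DR_PMC = 12
P_W_D2_GPE = 13
P_W_STN_GPE = 14
P_W_GPE_STN = 15
P_W_HD = 16
P_W_D1_GPI = 17
P_W_STN_GPI = 18  # signed: negative when the printed (inhibitory) sign is used
P_W_GPI_PFC = 19
P_W_PFC_PFC = 20
P_W_PFC_PMC = 21
P_W_GPI_PMC = 22
P_W_PMC_PMC = 23
P_LAM_DMS_D1 = 24
P_LAM_DMS_D2 = 25
P_LAM_DLS_D1 = 26
P_LAM_DLS_D2 = 27
P_DECAY = 28
P_W0 = 29
P_ALPHA = 30
P_MIX = 31
P_RECT_ABS = 32
N_PARAMS = 33

# plastic-weight vector layout
W_PFC_D1 = 0  # +channel
W_PFC_D2 = 2
W_PMC_D1 = 4
W_PMC_D2 = 6


@njit(cache=True)
def _sigma(i):
    if i <= 0.0:
        return 0.0
    return math.tanh(i)


@njit(cache=True)
def _run_trial(w, pv, impaired, n_steps):
    """Integrate one trial from rest; np.random must be seeded by the caller.

    Returns (state24, outcome, action) with 1-based selections.
    """
    d1m0 = 0.0; d1m1 = 0.0; d1l0 = 0.0; d1l1 = 0.0
    d2m0 = 0.0; d2m1 = 0.0; d2l0 = 0.0; d2l1 = 0.0
    gem0 = 0.0; gem1 = 0.0; gel0 = 0.0; gel1 = 0.0
    stm0 = 0.0; stm1 = 0.0; stl0 = 0.0; stl1 = 0.0
    gim0 = 0.0; gim1 = 0.0; gil0 = 0.0; gil1 = 0.0
    p0 = 0.0; p1 = 0.0
    m0 = 0.0; m1 = 0.0

    amp = pv[P_NOISE_AMP]
    if pv[P_NOISE_CENTERED] > 0.5:
        lo = -0.5 * amp
        hi = 0.5 * amp
    else:
        lo = 0.0
        hi = amp
    dt = pv[P_DT]
    ks = dt / pv[P_TAU_STN]
    kg = dt / pv[P_TAU_GPE]
    kd = dt / pv[P_TAU_DEFAULT]
    mix = pv[P_MIX] if impaired else 0.0
    keep = 1.0 - mix

    g_pfc = pv[P_G_PFC]; g_pmc = pv[P_G_PMC]
    dr_gpe = pv[P_DR_GPE]; dr_stn = pv[P_DR_STN]; dr_gpi = pv[P_DR_GPI]
    dr_pfc = pv[P_DR_PFC]; dr_pmc = pv[P_DR_PMC]
    w_d2_gpe = pv[P_W_D2_GPE]; w_stn_gpe = pv[P_W_STN_GPE]
    w_gpe_stn = pv[P_W_GPE_STN]; w_hd = pv[P_W_HD]
    w_d1_gpi = pv[P_W_D1_GPI]; w_stn_gpi = pv[P_W_STN_GPI]
    w_gpi_pfc = pv[P_W_GPI_PFC]; w_pfc_pfc = pv[P_W_PFC_PFC]
    w_pfc_pmc = pv[P_W_PFC_PMC]; w_gpi_pmc = pv[P_W_GPI_PMC]
    w_pmc_pmc = pv[P_W_PMC_PMC]

    wfd10 = w[W_PFC_D1]; wfd11 = w[W_PFC_D1 + 1]
    wfd20 = w[W_PFC_D2]; wfd21 = w[W_PFC_D2 + 1]
    wmd10 = w[W_PMC_D1]; wmd11 = w[W_PMC_D1 + 1]
    wmd20 = w[W_PMC_D2]; wmd21 = w[W_PMC_D2 + 1]

    for _ in range(n_steps):
        e0 = keep * p0 + mix * p1
        e1 = keep * p1 + mix * p0

        c_d1m0 = g_pfc * wfd10 * e0
        c_d1m1 = g_pfc * wfd11 * e1
        c_d1l0 = g_pmc * wmd10 * m0
        c_d1l1 = g_pmc * wmd11 * m1
        c_d2m0 = g_pfc * wfd20 * e0
        c_d2m1 = g_pfc * wfd21 * e1
        c_d2l0 = g_pmc * wmd20 * m0
        c_d2l1 = g_pmc * wmd21 * m1
        c_gem0 = dr_gpe - w_d2_gpe * d2m0 + w_stn_gpe * stm0
        c_gem1 = dr_gpe - w_d2_gpe * d2m1 + w_stn_gpe * stm1
        c_gel0 = dr_gpe - w_d2_gpe * d2l0 + w_stn_gpe * stl0
        c_gel1 = dr_gpe - w_d2_gpe * d2l1 + w_stn_gpe * stl1
        c_stm0 = dr_stn - w_gpe_stn * gem0
        c_stm1 = dr_stn - w_gpe_stn * gem1
        c_stl0 = dr_stn - w_gpe_stn * gel0 + w_hd * m0
        c_stl1 = dr_stn - w_gpe_stn * gel1 + w_hd * m1
        c_gim0 = dr_gpi - w_d1_gpi * d1m0 + w_stn_gpi * stm0
        c_gim1 = dr_gpi - w_d1_gpi * d1m1 + w_stn_gpi * stm1
        c_gil0 = dr_gpi - w_d1_gpi * d1l0 + w_stn_gpi * stl0
        c_gil1 = dr_gpi - w_d1_gpi * d1l1 + w_stn_gpi * stl1
        gf0 = keep * gim0 + mix * gim1
        gf1 = keep * gim1 + mix * gim0
        c_p0 = dr_pfc - w_gpi_pfc * gf0 - w_pfc_pfc * p1
        c_p1 = dr_pfc - w_gpi_pfc * gf1 - w_pfc_pfc * p0
        c_m0 = dr_pmc + w_pfc_pmc * e0 - w_gpi_pmc * gil0 - w_pmc_pmc * m1
        c_m1 = dr_pmc + w_pfc_pmc * e1 - w_gpi_pmc * gil1 - w_pmc_pmc * m0

        # synchronous update; noise drawn in canonical state order
        d1m0 += kd * (_sigma(c_d1m0) - d1m0 + np.random.uniform(lo, hi))
        d1m1 += kd * (_sigma(c_d1m1) - d1m1 + np.random.uniform(lo, hi))
        d1l0 += kd * (_sigma(c_d1l0) - d1l0 + np.random.uniform(lo, hi))
        d1l1 += kd * (_sigma(c_d1l1) - d1l1 + np.random.uniform(lo, hi))
        d2m0 += kd * (_sigma(c_d2m0) - d2m0 + np.random.uniform(lo, hi))
        d2m1 += kd * (_sigma(c_d2m1) - d2m1 + np.random.uniform(lo, hi))
        d2l0 += kd * (_sigma(c_d2l0) - d2l0 + np.random.uniform(lo, hi))
        d2l1 += kd * (_sigma(c_d2l1) - d2l1 + np.random.uniform(lo, hi))
        gem0 += kg * (_sigma(c_gem0) - gem0 + np.random.uniform(lo, hi))
        gem1 += kg * (_sigma(c_gem1) - gem1 + np.random.uniform(lo, hi))
        gel0 += kg * (_sigma(c_gel0) - gel0 + np.random.uniform(lo, hi))
        gel1 += kg * (_sigma(c_gel1) - gel1 + np.random.uniform(lo, hi))
        stm0 += ks * (_sigma(c_stm0) - stm0 + np.random.uniform(lo, hi))
        stm1 += ks * (_sigma(c_stm1) - stm1 + np.random.uniform(lo, hi))
        stl0 += ks * (_sigma(c_stl0) - stl0 + np.random.uniform(lo, hi))
        stl1 += ks * (_sigma(c_stl1) - stl1 + np.random.uniform(lo, hi))
        gim0 += kd * (_sigma(c_gim0) - gim0 + np.random.uniform(lo, hi))
        gim1 += kd * (_sigma(c_gim1) - gim1 + np.random.uniform(lo, hi))
        gil0 += kd * (_sigma(c_gil0) - gil0 + np.random.uniform(lo, hi))
        gil1 += kd * (_sigma(c_gil1) - gil1 + np.random.uniform(lo, hi))
        p0 += kd * (_sigma(c_p0) - p0 + np.random.uniform(lo, hi))
        p1 += kd * (_sigma(c_p1) - p1 + np.random.uniform(lo, hi))
        m0 += kd * (_sigma(c_m0) - m0 + np.random.uniform(lo, hi))
        m1 += kd * (_sigma(c_m1) - m1 + np.random.uniform(lo, hi))

    state = np.empty(24)
    state[0] = d1m0; state[1] = d1m1; state[2] = d1l0; state[3] = d1l1
    state[4] = d2m0; state[5] = d2m1; state[6] = d2l0; state[7] = d2l1
    state[8] = gem0; state[9] = gem1; state[10] = gel0; state[11] = gel1
    state[12] = stm0; state[13] = stm1; state[14] = stl0; state[15] = stl1
    state[16] = gim0; state[17] = gim1; state[18] = gil0; state[19] = gil1
    state[20] = p0; state[21] = p1
    state[22] = m0; state[23] = m1

    if p0 > p1:
        outcome = 1
    elif p1 > p0:
        outcome = 2
    else:
        outcome = 1 if np.random.uniform(0.0, 1.0) < 0.5 else 2
    if m0 > m1:
        action = 1
    elif m1 > m0:
        action = 2
    else:
        action = 1 if np.random.uniform(0.0, 1.0) < 0.5 else 2
    return state, outcome, action


@njit(cache=True)
def trial(w, pv, impaired, n_steps, seed):
    """Seed the generator and run a single trial (public kernel entry)."""
    np.random.seed(seed)
    return _run_trial(w, pv, impaired, n_steps)


@njit(cache=True)
def run_session(w, exp_rew, rect_exp, pv, reward1, reward2, impaired,
                n_steps, trial_seeds):
    """Run a full session: trial loop with between-trial plasticity.

    ``w`` is modified in place (pass a copy to preserve the input).  Returns
    per-trial logs plus the final reward trace.  Trial j is seeded from
    ``trial_seeds[j]`` so any single trial can be reproduced in isolation.
    """
    n_trials = trial_seeds.shape[0]
    alpha = pv[P_ALPHA]
    lam_fd1 = pv[P_LAM_DMS_D1]; lam_fd2 = pv[P_LAM_DMS_D2]
    lam_md1 = pv[P_LAM_DLS_D1]; lam_md2 = pv[P_LAM_DLS_D2]
    dec = pv[P_DECAY]; w0 = pv[P_W0]
    mix = pv[P_MIX] if impaired else 0.0
    keep = 1.0 - mix
    use_abs = pv[P_RECT_ABS] > 0.5

    outcomes = np.empty(n_trials, np.int64)
    actions = np.empty(n_trials, np.int64)
    rewards = np.empty(n_trials)
    exp_log = np.empty(n_trials)
    rect_log = np.empty(n_trials)
    snc_log = np.empty(n_trials)
    rates_log = np.empty((n_trials, 4))   # pfc1 pfc2 pmc1 pmc2
    w_log = np.empty((n_trials, 8))       # post-update snapshot

    for j in range(n_trials):
        np.random.seed(trial_seeds[j])
        state, outcome, action = _run_trial(w, pv, impaired, n_steps)
        reward = reward1 if action == 1 else reward2

        # dopamine signals use the pre-update traces
        snc_dms = reward - exp_rew
        snc_dls = rect_exp
        exp_rew = alpha * reward + (1.0 - alpha) * exp_rew
        r_sal = abs(reward) if use_abs else reward
        rect_exp = alpha * r_sal + (1.0 - alpha) * rect_exp

        pfc0 = state[20]; pfc1 = state[21]
        pmc0 = state[22]; pmc1 = state[23]
        e0 = keep * pfc0 + mix * pfc1
        e1 = keep * pfc1 + mix * pfc0

        # three-factor updates, both channels every trial, decay toward w0
        w[W_PFC_D1] += lam_fd1 * snc_dms * e0 * state[0] - dec * (w[W_PFC_D1] - w0)
        w[W_PFC_D1 + 1] += lam_fd1 * snc_dms * e1 * state[1] - dec * (w[W_PFC_D1 + 1] - w0)
        w[W_PFC_D2] += -lam_fd2 * snc_dms * e0 * state[4] - dec * (w[W_PFC_D2] - w0)
        w[W_PFC_D2 + 1] += -lam_fd2 * snc_dms * e1 * state[5] - dec * (w[W_PFC_D2 + 1] - w0)
        w[W_PMC_D1] += lam_md1 * snc_dls * pmc0 * state[2] - dec * (w[W_PMC_D1] - w0)
        w[W_PMC_D1 + 1] += lam_md1 * snc_dls * pmc1 * state[3] - dec * (w[W_PMC_D1 + 1] - w0)
        w[W_PMC_D2] += -lam_md2 * snc_dls * pmc0 * state[6] - dec * (w[W_PMC_D2] - w0)
        w[W_PMC_D2 + 1] += -lam_md2 * snc_dls * pmc1 * state[7] - dec * (w[W_PMC_D2 + 1] - w0)
        for k in range(8):
            if w[k] < 0.0:
                w[k] = 0.0

        outcomes[j] = outcome
        actions[j] = action
        rewards[j] = reward
        exp_log[j] = exp_rew
        rect_log[j] = rect_exp
        snc_log[j] = snc_dms
        rates_log[j, 0] = pfc0; rates_log[j, 1] = pfc1
        rates_log[j, 2] = pmc0; rates_log[j, 3] = pmc1
        for k in range(8):
            w_log[j, k] = w[k]

    return (outcomes, actions, rewards, exp_log, rect_log, snc_log,
            rates_log, w_log, exp_rew, rect_exp)


@njit(cache=True)
def count_selections(weights_series, pv, impaired, n_steps, rep_seeds):
    """Repeat each cached-weight trial many times; count channel-1 picks.

    ``weights_series`` is (n_trials, 8); ``rep_seeds`` is (n_trials, n_reps).
    Returns an (n_trials, 2) int64 array: column 0 counts outcome #1 (PFC),
    column 1 counts action #1 (PMC).
    """
    n_trials = weights_series.shape[0]
    n_reps = rep_seeds.shape[1]
    counts = np.zeros((n_trials, 2), np.int64)
    for j in range(n_trials):
        wj = weights_series[j].copy()
        for r in range(n_reps):
            np.random.seed(rep_seeds[j, r])
            _, outcome, action = _run_trial(wj, pv, impaired, n_steps)
            if outcome == 1:
                counts[j, 0] += 1
            if action == 1:
                counts[j, 1] += 1
    return counts
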