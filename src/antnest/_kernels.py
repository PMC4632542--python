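"""Numba-compiled inner loops shared by the ODE and stochastic engines.

Both models are expressed through the same fifteen transition channels; a
channel moves one ant (one unit of density in the ODE) from a source to a
destination compartment.  State vectors are float64 arrays of length nine in
the compartment order below; stochastic engines keep exactly-integral floats.

Compartment order::

    0 LC     low-threshold, home nest
    1 HC     high-threshold, home nest
    2 LPCOM  low-threshold, committed to poor site
    3 HPVIS  high-threshold, visiting poor site (uncommitted)
    4 LGCOM  low-threshold, committed to good site
    5 HGCOM  high-threshold, committed to good site
    6 LPREC  low-threshold, recruiting to poor site
    7 LGREC  low-threshold, recruiting to good site
    8 HGREC  high-threshold, recruiting to good site
"""

from __future__ import annotations

import numpy as np
from numba import njit

LC, HC, LPCOM, HPVIS, LGCOM, HGCOM, LPREC, LGREC, HGREC = range(9)

N_CHANNELS = 15

# channel -> (source, destination)
CHANNEL_SRC = np.array(
    [LC, LC, HC, HC, LPCOM, LGCOM, HGCOM, HPVIS,
     LPCOM, HPVIS, LGCOM, HGCOM, LPREC, LGREC, HGREC],
    dtype=np.int64,
)
CHANNEL_DST = np.array(
    [LPCOM, LGCOM, HPVIS, HGCOM, LPREC, LGREC, HGREC, HGCOM,
     LC, HC, LC, HC, LC, LC, HC],
    dtype=np.int64,
)

CHANNEL_NAMES = (
    "recruit:lc->lpcom",
    "recruit:lc->lgcom",
    "recruit:hc->hpvis",
    "recruit:hc->hgcom",
    "convert:lpcom->lprec",
    "convert:lgcom->lgrec",
    "convert:hgcom->hgrec",
    "switch:hpvis->hgcom",
    "leak:lpcom->lc",
    "leak:hpvis->hc",
    "leak:lgcom->lc",
    "leak:hgcom->hc",
    "leak:lprec->lc",
    "leak:lgrec->lc",
    "leak:hgrec->hc",
)

# Run outcome codes shared by all engines.
GOOD_QUORUM, POOR_QUORUM, UNSUCCESSFUL, CENSORED = 0, 1, 2, 3


@njit(cache=True)
def channel_rates(c, alpha_p, alpha_g, alpha_s, alpha_leak, n, out):
    """Fill `out` (length 15) with the channel rates for state `c`.

    `n` is the mass-action normalization: the colony size for count states,
    1.0 for density states (the ODE).
    """
    rec_good = c[LGREC] + c[HGREC]
    out[0] = c[LC] * c[LPREC] / n
    out[1] = c[LC] * rec_good / n
    out[2] = c[HC] * c[LPREC] / n
    out[3] = c[HC] * rec_good / n
    out[4] = alpha_p * c[LPCOM]
    out[5] = alpha_g * c[LGCOM]
    out[6] = alpha_g * c[HGCOM]
    out[7] = alpha_s * c[HPVIS]
    out[8] = alpha_leak * c[LPCOM]
    out[9] = alpha_leak * c[HPVIS]
    out[10] = alpha_leak * c[LGCOM]
    out[11] = alpha_leak * c[HGCOM]
    out[12] = alpha_leak * c[LPREC]
    out[13] = alpha_leak * c[LGREC]
    out[14] = alpha_leak * c[HGREC]


@njit(cache=True)
def rhs(c, alpha_p, alpha_g, alpha_s, alpha_leak, out):
    """Mean-field time derivative of the nine compartment densities."""
    r = np.empty(N_CHANNELS)
    channel_rates(c, alpha_p, alpha_g, alpha_s, alpha_leak, 1.0, r)
    for i in range(9):
        out[i] = 0.0
    for k in range(N_CHANNELS):
        out[CHANNEL_SRC[k]] -= r[k]
        out[CHANNEL_DST[k]] += r[k]


@njit(cache=True)
def _votes_good(c):
    return c[LGCOM] + c[HGCOM] + c[LGREC] + c[HGREC]


@njit(cache=True)
def _votes_poor(c):
    return c[LPCOM] + c[LPREC] + c[HPVIS]


@njit(cache=True)
def euler_integrate(c0, alpha_p, alpha_g, alpha_s, alpha_leak,
                    dt, n_steps, stride, quorum_fraction):
    """Forward-Euler integration with full-resolution quorum detection.

    Returns (times, states, t_quorum, site, min_component) where `states`
    holds every `stride`-th step (plus the final one), `t_quorum` is the
    earliest step time at which either vote reaches `quorum_fraction`
    (-1.0 if never), `site` is +1 (good) / -1 (poor) / 0, and
    `min_component` is the most negative value any compartment ever took.
    """
    n_rec = 1 + n_steps // stride + (1 if n_steps % stride else 0)
    times = np.empty(n_rec)
    states = np.empty((n_rec, 9))
    c = c0.copy()
    r = np.empty(N_CHANNELS)
    d = np.empty(9)
    times[0] = 0.0
    states[0] = c
    idx = 1
    t_quorum = -1.0
    site = 0
    min_component = 0.0
    for i in range(9):
        if c[i] < min_component:
            min_component = c[i]
    for k in range(1, n_steps + 1):
        channel_rates(c, alpha_p, alpha_g, alpha_s, alpha_leak, 1.0, r)
        for i in range(9):
            d[i] = 0.0
        for j in range(N_CHANNELS):
            d[CHANNEL_SRC[j]] -= r[j]
            d[CHANNEL_DST[j]] += r[j]
        for i in range(9):
            c[i] += dt * d[i]
            if c[i] < min_component:
                min_component = c[i]
        if t_quorum < 0.0:
            if _votes_good(c) >= quorum_fraction:
                t_quorum = k * dt
                site = 1
            elif _votes_poor(c) >= quorum_fraction:
                t_quorum = k * dt
                site = -1
        if k % stride == 0 or k == n_steps:
            times[idx] = k * dt
            states[idx] = c
            idx += 1
    return times[:idx], states[:idx], t_quorum, site, min_component


@njit(cache=True)
def ssa_one(c, alpha_p, alpha_g, alpha_s, alpha_leak, n, quorum, t_max):
    """One exact event-driven run; `c` (counts as floats) is mutated.

    Returns (code, time, n_events).  Codes: 0 good quorum, 1 poor quorum,
    2 unsuccessful (all ants home, total rate zero), 3 censored.
    """
    r = np.empty(N_CHANNELS)
    t = 0.0
    n_events = 0
    while True:
        channel_rates(c, alpha_p, alpha_g, alpha_s, alpha_leak, n, r)
        total = 0.0
        for j in range(N_CHANNELS):
            total += r[j]
        if total <= 0.0:
            if c[LC] + c[HC] >= n:
                return UNSUCCESSFUL, t, n_events
            return CENSORED, t, n_events
        u1 = 1.0 - np.random.random()  # in (0, 1]
        t_next = t - np.log(u1) / total
        if t_next > t_max:
            return CENSORED, t_max, n_events
        t = t_next
        u2 = np.random.random() * total
        acc = 0.0
        k = N_CHANNELS - 1
        for j in range(N_CHANNELS):
            acc += r[j]
            if u2 < acc:
                k = j
                break
        c[CHANNEL_SRC[k]] -= 1.0
        c[CHANNEL_DST[k]] += 1.0
        n_events += 1
        if _votes_good(c) >= quorum:
            return GOOD_QUORUM, t, n_events
        if _votes_poor(c) >= quorum:
            return POOR_QUORUM, t, n_events


@njit(cache=True)
def ssa_batch(c0, alpha_p, alpha_g, alpha_s, alpha_leak, n, quorum, t_max, seeds):
    """Independent event-driven runs, one per seed."""
    n_runs = seeds.shape[0]
    codes = np.empty(n_runs, dtype=np.int64)
    times = np.empty(n_runs)
    n_events = np.empty(n_runs, dtype=np.int64)
    c = np.empty(9)
    for i in range(n_runs):
        np.random.seed(seeds[i])
        c[:] = c0
        code, t, ne = ssa_one(c, alpha_p, alpha_g, alpha_s, alpha_leak,
                              n, quorum, t_max)
        codes[i] = code
        times[i] = t
        n_events[i] = ne
    return codes, times, n_events


@njit(cache=True)
def ssa_record(c0, alpha_p, alpha_g, alpha_s, alpha_leak, n, grid, seed):
    """Event-driven run without quorum stopping, sampled on a time grid.

    Returns states (len(grid), 9): the state holding at each grid time.
    If the process absorbs, the absorbing state fills the rest of the grid.
    """
    np.random.seed(seed)
    c = c0.copy()
    out = np.empty((grid.shape[0], 9))
    r = np.empty(N_CHANNELS)
    t = 0.0
    gi = 0
    while gi < grid.shape[0]:
        channel_rates(c, alpha_p, alpha_g, alpha_s, alpha_leak, n, r)
        total = 0.0
        for j in range(N_CHANNELS):
            total += r[j]
        if total <= 0.0:
            for g in range(gi, grid.shape[0]):
                out[g] = c
            break
        u1 = 1.0 - np.random.random()
        t_next = t - np.log(u1) / total
        while gi < grid.shape[0] and grid[gi] < t_next:
            out[gi] = c
            gi += 1
        if gi >= grid.shape[0]:
            break
        t = t_next
        u2 = np.random.random() * total
        acc = 0.0
        k = N_CHANNELS - 1
        for j in range(N_CHANNELS):
            acc += r[j]
            if u2 < acc:
                k = j
                break
        c[CHANNEL_SRC[k]] -= 1.0
        c[CHANNEL_DST[k]] += 1.0
    return out


@njit(cache=True)
def _binom2(n, p1, p2):
    """Draw (n1, n2) from a multinomial(n; p1, p2, 1-p1-p2) via two binomials."""
    n1 = np.random.binomial(n, p1) if p1 > 0.0 else 0
    rest = 1.0 - p1
    n2 = 0
    if rest > 0.0 and p2 > 0.0 and n - n1 > 0:
        n2 = np.random.binomial(n - n1, p2 / rest)
    return n1, n2


@njit(cache=True)
def discrete_one(c, alpha_p, alpha_g, alpha_s, alpha_leak, n, quorum, dt, t_max):
    """One fixed-step run: per-ant Bernoulli transitions per time step.

    Each ant acts independently each step; an ant performs at most one
    transition per step (competing moves drawn as a multinomial).  Mutates
    `c`; returns (code, time, n_steps).
    """
    n_steps = int(np.ceil(t_max / dt))
    for k in range(1, n_steps + 1):
        rec_good = c[LGREC] + c[HGREC]
        p_rp = c[LPREC] / n * dt   # recruited towards poor site
        p_rg = rec_good / n * dt   # recruited towards good site
        p_cp = alpha_p * dt
        p_cg = alpha_g * dt
        p_sw = alpha_s * dt
        p_lk = alpha_leak * dt

        lc_p, lc_g = _binom2(int(c[LC]), p_rp, p_rg)
        hc_p, hc_g = _binom2(int(c[HC]), p_rp, p_rg)
        lp_conv, lp_leak = _binom2(int(c[LPCOM]), p_cp, p_lk)
        hp_sw, hp_leak = _binom2(int(c[HPVIS]), p_sw, p_lk)
        lg_conv, lg_leak = _binom2(int(c[LGCOM]), p_cg, p_lk)
        hg_conv, hg_leak = _binom2(int(c[HGCOM]), p_cg, p_lk)
        lpr_leak, _ = _binom2(int(c[LPREC]), p_lk, 0.0)
        lgr_leak, _ = _binom2(int(c[LGREC]), p_lk, 0.0)
        hgr_leak, _ = _binom2(int(c[HGREC]), p_lk, 0.0)

        c[LC] += lp_leak + lg_leak + lpr_leak + lgr_leak - lc_p - lc_g
        c[HC] += hp_leak + hg_leak + hgr_leak - hc_p - hc_g
        c[LPCOM] += lc_p - lp_conv - lp_leak
        c[HPVIS] += hc_p - hp_sw - hp_leak
        c[LGCOM] += lc_g - lg_conv - lg_leak
        c[HGCOM] += hc_g + hp_sw - hg_conv - hg_leak
        c[LPREC] += lp_conv - lpr_leak
        c[LGREC] += lg_conv - lgr_leak
        c[HGREC] += hg_conv - hgr_leak

        if _votes_good(c) >= quorum:
            return GOOD_QUORUM, k * dt, k
        if _votes_poor(c) >= quorum:
            return POOR_QUORUM, k * dt, k
        if c[LC] + c[HC] >= n:
            return UNSUCCESSFUL, k * dt, k
    return CENSORED, t_max, n_steps


@njit(cache=True)
def discrete_batch(c0, alpha_p, alpha_g, alpha_s, alpha_leak, n, quorum,
                   dt, t_max, seeds):
    n_runs = seeds.shape[0]
    codes = np.empty(n_runs, dtype=np.int64)
    times = np.empty(n_runs)
    n_steps = np.empty(n_runs, dtype=np.int64)
    c = np.empty(9)
    for i in range(n_runs):
        np.random.seed(seeds[i])
        c[:] = c0
        code, t, ns = discrete_one(c, alpha_p, alpha_g, alpha_s, alpha_leak,
                                   n, quorum, dt, t_max)
        codes[i] = code
        times[i] = t
        n_steps[i] = ns
    return codes, times, n_steps


# Multi-site (cohesion) engine.  Outcome codes reuse the constants above,
# with GOOD_QUORUM standing for "finished".
FINISHED = GOOD_QUORUM


@njit(cache=True)
def cohesion_one(home0, com0, rec0, alpha, alpha_leak, n, finish_count, t_max):
    """One event-driven multi-site emigration run.

    Channels per site i: recruit home->committed_i at home*rec_i/N,
    convert committed_i->recruiter_i at alpha, leak either back home at
    alpha_leak.  Stops when the number of emigrants (N - home) reaches
    `finish_count`.  Returns (code, time, n_events, site_occupancy).
    """
    n_nest = com0.shape[0]
    com = com0.astype(np.float64).copy()
    rec = rec0.astype(np.float64).copy()
    home = float(home0)
    rates = np.empty(4 * n_nest)
    t = 0.0
    n_events = 0
    while True:
        total = 0.0
        for i in range(n_nest):
            rates[4 * i] = home * rec[i] / n
            rates[4 * i + 1] = alpha * com[i]
            rates[4 * i + 2] = alpha_leak * com[i]
            rates[4 * i + 3] = alpha_leak * rec[i]
            total += rates[4 * i] + rates[4 * i + 1] + rates[4 * i + 2] + rates[4 * i + 3]
        if total <= 0.0:
            occ = com + rec
            if home >= n:
                return UNSUCCESSFUL, t, n_events, occ
            return CENSORED, t, n_events, occ
        u1 = 1.0 - np.random.random()
        t_next = t - np.log(u1) / total
        if t_next > t_max:
            return CENSORED, t_max, n_events, com + rec
        t = t_next
        u2 = np.random.random() * total
        acc = 0.0
        k = 4 * n_nest - 1
        for j in range(4 * n_nest):
            acc += rates[j]
            if u2 < acc:
                k = j
                break
        site = k // 4
        kind = k % 4
        if kind == 0:
            home -= 1.0
            com[site] += 1.0
        elif kind == 1:
            com[site] -= 1.0
            rec[site] += 1.0
        elif kind == 2:
            com[site] -= 1.0
            home += 1.0
        else:
            rec[site] -= 1.0
            home += 1.0
        n_events += 1
        if n - home >= finish_count:
            return FINISHED, t, n_events, com + rec


@njit(cache=True)
def cohesion_batch(home0, com0, rec0, alpha, alpha_leak, n, finish_count,
                   t_max, seeds):
    n_runs = seeds.shape[0]
    n_nest = com0.shape[0]
    codes = np.empty(n_runs, dtype=np.int64)
    times = np.empty(n_runs)
    occupancy = np.empty((n_runs, n_nest))
    for i in range(n_runs):
        np.random.seed(seeds[i])
        code, t, _, occ = cohesion_one(home0, com0, rec0, alpha, alpha_leak,
                                       n, finish_count, t_max)
        codes[i] = code
        times[i] = t
        occupancy[i] = occ
    return codes, times, occupancy
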