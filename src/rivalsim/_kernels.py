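"""Compiled simulation kernels (numba).

The stochastic model advances four Ehrenfest pools in discrete time steps;
at dt = 0.5 ms and simulated hours of rivalry this is far too slow in pure
Python, so the inner loops live here as ``@njit`` functions.  The public API
in :mod:`rivalsim.core` and :mod:`rivalsim.stats` wraps these kernels.

All kernels take plain scalars (pool size, rates, couplings, drives) so the
compiled signatures stay simple.  Randomness uses numba's internal RNG,
seeded explicitly at the top of every kernel for bit-exact reproducibility.

Rate-to-probability mapping: a variable with Poisson rate ``nu`` flips
within a step of length dt with probability ``1 - exp(-nu * dt)`` (the exact
exponential waiting-time mapping).  This equals ``nu * dt`` to first order
but remains a valid probability for the very large decision-pool rates that
occur during reversals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# pool update -----------------------------------------------------------


@njit(inline="always", cache=True)
def _flip_prob(nu, dt):
    # 1 - exp(-nu dt), safe for huge rates
    x = nu * dt
    if x > 40.0:
        return 1.0
    return -np.expm1(-x)


@njit(inline="always", cache=True)
def _pool_step(N, n, nu_base, du, dt):
    """Binomial birth-death increment of one pool; returns the new count."""
    half = 0.5 * du
    # clip the exponent: beyond +-60 the probabilities saturate anyway
    if half > 60.0:
        half = 60.0
    elif half < -60.0:
        half = -60.0
    nu_p = 0.5 * nu_base * np.exp(half)
    nu_m = 0.5 * nu_base * np.exp(-half)
    p_up = _flip_prob(nu_p, dt)
    p_dn = _flip_prob(nu_m, dt)
    up = 0
    dn = 0
    if N - n > 0 and p_up > 0.0:
        up = np.random.binomial(N - n, p_up)
    if n > 0 and p_dn > 0.0:
        dn = np.random.binomial(n, p_dn)
    return n + up - dn


@njit(cache=True)
def sim_trajectory(
    N,
    nu_e,
    nu_r,
    ue0,
    ur0,
    w_vis,
    w_exc,
    w_inh,
    w_comp,
    w_coop,
    w_supp,
    I1,
    I2,
    dt,
    n_steps,
    record_every,
    seed,
    start_first,
    ne0,
    ne20,
    nr0,
    nr20,
):
    """Simulate the four coupled pools, recording fractional activities.

    ``start_first`` selects which decision pool starts fully active when the
    initial counts are the defaults (-1 in all four slots); otherwise the
    explicit counts are used.  Returns an array of shape (4, n_records) with
    rows e, e', r, r'.
    """
    np.random.seed(seed)
    if ne0 < 0:
        n_e = 0
        n_e2 = 0
        if start_first:
            n_r = N
            n_r2 = 0
        else:
            n_r = 0
            n_r2 = N
    else:
        n_e = ne0
        n_e2 = ne20
        n_r = nr0
        n_r2 = nr20
    n_rec = n_steps // record_every + 1
    out = np.empty((4, n_rec))
    out[0, 0] = n_e / N
    out[1, 0] = n_e2 / N
    out[2, 0] = n_r / N
    out[3, 0] = n_r2 / N
    k = 1
    for step in range(1, n_steps + 1):
        e = n_e / N
        e2 = n_e2 / N
        r = n_r / N
        r2 = n_r2 / N
        du_e = w_vis * I1 - w_supp * r + ue0
        du_e2 = w_vis * I2 - w_supp * r2 + ue0
        fwd = w_inh * (e + e2)
        du_r = w_exc * e - fwd + w_coop * r - w_comp * r2 + ur0
        du_r2 = w_exc * e2 - fwd + w_coop * r2 - w_comp * r + ur0
        n_e = _pool_step(N, n_e, nu_e, du_e, dt)
        n_e2 = _pool_step(N, n_e2, nu_e, du_e2, dt)
        n_r = _pool_step(N, n_r, nu_r, du_r, dt)
        n_r2 = _pool_step(N, n_r2, nu_r, du_r2, dt)
        if step % record_every == 0:
            out[0, k] = n_e / N
            out[1, k] = n_e2 / N
            out[2, k] = n_r / N
            out[3, k] = n_r2 / N
            k += 1
    return out


@njit(cache=True)
def sim_periods(
    N,
    nu_e,
    nu_r,
    ue0,
    ur0,
    w_vis,
    w_exc,
    w_inh,
    w_comp,
    w_coop,
    w_supp,
    I1,
    I2,
    dt,
    burn_in,
    hi,
    lo,
    n_periods,
    max_steps,
    seed,
    start_first,
):
    """Simulate until ``n_periods`` completed dominance periods are collected.

    Dominance is tracked online with a hysteresis state machine on the
    decision fractions (confirm when one fraction >= ``hi`` while the other
    <= ``lo``); the reversal instant is the most recent zero crossing of
    r - r' before the new state is confirmed.  Periods starting before
    ``burn_in`` are discarded.

    Returns (durations, labels, e_at_end, e2_at_end, n_found, t_end) where
    label +1 means the first pool (image contrast I1) was dominant and the
    evidence fractions are sampled at the reversal terminating each period.
    """
    np.random.seed(seed)
    n_e = 0
    n_e2 = 0
    if start_first:
        n_r = N
        n_r2 = 0
    else:
        n_r = 0
        n_r2 = N
    durations = np.empty(n_periods)
    labels = np.empty(n_periods, np.int8)
    e_end = np.empty(n_periods)
    e2_end = np.empty(n_periods)
    count = 0
    cur = 0  # confirmed dominant pool: +1, -1, or 0 before first confirmation
    prev_rev_t = -1.0
    cross_t = 0.0
    cross_e = 0.0
    cross_e2 = 0.0
    prev_d = n_r - n_r2
    t = 0.0
    for _ in range(max_steps):
        e = n_e / N
        e2 = n_e2 / N
        r = n_r / N
        r2 = n_r2 / N
        du_e = w_vis * I1 - w_supp * r + ue0
        du_e2 = w_vis * I2 - w_supp * r2 + ue0
        fwd = w_inh * (e + e2)
        du_r = w_exc * e - fwd + w_coop * r - w_comp * r2 + ur0
        du_r2 = w_exc * e2 - fwd + w_coop * r2 - w_comp * r + ur0
        n_e = _pool_step(N, n_e, nu_e, du_e, dt)
        n_e2 = _pool_step(N, n_e2, nu_e, du_e2, dt)
        n_r = _pool_step(N, n_r, nu_r, du_r, dt)
        n_r2 = _pool_step(N, n_r2, nu_r, du_r2, dt)
        t += dt
        d = n_r - n_r2
        if (d > 0 and prev_d <= 0) or (d < 0 and prev_d >= 0):
            cross_t = t
            cross_e = n_e / N
            cross_e2 = n_e2 / N
        prev_d = d
        conf = 0
        if n_r >= hi * N and n_r2 <= lo * N:
            conf = 1
        elif n_r2 >= hi * N and n_r <= lo * N:
            conf = -1
        if conf != 0 and conf != cur:
            if cur != 0:
                # period of percept `cur` ended at the last zero crossing
                if prev_rev_t >= burn_in:
                    durations[count] = cross_t - prev_rev_t
                    labels[count] = cur
                    e_end[count] = cross_e
                    e2_end[count] = cross_e2
                    count += 1
                    if count >= n_periods:
                        cur = conf
                        break
                prev_rev_t = cross_t
            else:
                prev_rev_t = cross_t if cross_t > 0.0 else t
            cur = conf
    return durations[:count], labels[:count], e_end[:count], e2_end[:count], count, t


# mean-field ------------------------------------------------------------


@njit(inline="always", cache=True)
def _relax(x, nu_base, du, dt):
    """Exponential (integrating-factor) update of <x> with rates frozen."""
    half = 0.5 * du
    if half > 60.0:
        half = 60.0
    elif half < -60.0:
        half = -60.0
    nu_p = 0.5 * nu_base * np.exp(half)
    nu_m = 0.5 * nu_base * np.exp(-half)
    tot = nu_p + nu_m
    x_inf = nu_p / tot
    return x_inf + (x - x_inf) * np.exp(-tot * dt)


@njit(cache=True)
def meanfield_trajectory(
    nu_e,
    nu_r,
    ue0,
    ur0,
    w_vis,
    w_exc,
    w_inh,
    w_comp,
    w_coop,
    w_supp,
    I1,
    I2,
    dt,
    n_steps,
    record_every,
    e0,
    e20,
    r0,
    r20,
):
    """Deterministic (N -> infinity) limit of the four-pool dynamics.

    Each step freezes the rates at the current state and applies the exact
    linear relaxation towards the instantaneous asymptote, which is
    unconditionally stable even for the very fast decision rates reached
    during reversals.
    """
    e = e0
    e2 = e20
    r = r0
    r2 = r20
    n_rec = n_steps // record_every + 1
    out = np.empty((4, n_rec))
    out[0, 0] = e
    out[1, 0] = e2
    out[2, 0] = r
    out[3, 0] = r2
    k = 1
    for step in range(1, n_steps + 1):
        du_e = w_vis * I1 - w_supp * r + ue0
        du_e2 = w_vis * I2 - w_supp * r2 + ue0
        fwd = w_inh * (e + e2)
        du_r = w_exc * e - fwd + w_coop * r - w_comp * r2 + ur0
        du_r2 = w_exc * e2 - fwd + w_coop * r2 - w_comp * r + ur0
        e = _relax(e, nu_e, du_e, dt)
        e2 = _relax(e2, nu_e, du_e2, dt)
        r = _relax(r, nu_r, du_r, dt)
        r2 = _relax(r2, nu_r, du_r2, dt)
        if step % record_every == 0:
            out[0, k] = e
            out[1, k] = e2
            out[2, k] = r
            out[3, k] = r2
            k += 1
    return out


@njit(cache=True)
def decision_flip(
    nu_r,
    ur0,
    w_exc,
    w_inh,
    w_comp,
    w_coop,
    e,
    e2,
    dt,
    t_max,
):
    """Mean-field decision pools under frozen evidence (e, e2).

    Starts in the state contradicted by the evidence (r = 0 dominant pool
    r2 = 1) and integrates until either the state flips (returns the flip
    time) or ``t_max`` elapses (returns -1.0).
    """
    r = 0.0
    r2 = 1.0
    t = 0.0
    n_steps = int(t_max / dt)
    fwd = w_inh * (e + e2)
    for _ in range(n_steps):
        du_r = w_exc * e - fwd + w_coop * r - w_comp * r2 + ur0
        du_r2 = w_exc * e2 - fwd + w_coop * r2 - w_comp * r + ur0
        r = _relax(r, nu_r, du_r, dt)
        r2 = _relax(r2, nu_r, du_r2, dt)
        t += dt
        if r - r2 > 0.0:
            return t
    return -1.0


# alternative model -----------------------------------------------------


@njit(cache=True)
def sim_alt(
    beta,
    tau_r,
    tau_a,
    tau_n,
    phi_a,
    kappa,
    I1,
    I2,
    sig1,
    sig2,
    dt,
    n_steps,
    record_every,
    seed,
):
    """Euler integration of the adaptation model with exact OU noise updates.

    Returns an array of shape (6, n_records): r1, r2, a1, a2, n1, n2.
    """
    np.random.seed(seed)
    r1 = 0.5
    r2 = 0.5
    a1 = 0.0
    a2 = 0.0
    n1 = sig1 * np.random.normal()
    n2 = sig2 * np.random.normal()
    decay = np.exp(-dt / tau_n)
    kick1 = sig1 * np.sqrt(1.0 - decay * decay)
    kick2 = sig2 * np.sqrt(1.0 - decay * decay)
    n_rec = n_steps // record_every + 1
    out = np.empty((6, n_rec))
    out[0, 0] = r1
    out[1, 0] = r2
    out[2, 0] = a1
    out[3, 0] = a2
    out[4, 0] = n1
    out[5, 0] = n2
    k = 1
    for step in range(1, n_steps + 1):
        x1 = -beta * r2 - phi_a * a1 + I1 + n1
        x2 = -beta * r1 - phi_a * a2 + I2 + n2
        f1 = 1.0 / (1.0 + np.exp(-x1 / kappa)) if abs(x1 / kappa) < 500 else (1.0 if x1 > 0 else 0.0)
        f2 = 1.0 / (1.0 + np.exp(-x2 / kappa)) if abs(x2 / kappa) < 500 else (1.0 if x2 > 0 else 0.0)
        r1 += dt / tau_r * (-r1 + f1)
        r2 += dt / tau_r * (-r2 + f2)
        a1 += dt / tau_a * (-a1 + r1)
        a2 += dt / tau_a * (-a2 + r2)
        n1 = n1 * decay + kick1 * np.random.normal()
        n2 = n2 * decay + kick2 * np.random.normal()
        if step % record_every == 0:
            out[0, k] = r1
            out[1, k] = r2
            out[2, k] = a1
            out[3, k] = a2
            out[4, k] = n1
            out[5, k] = n2
            k += 1
    return out
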