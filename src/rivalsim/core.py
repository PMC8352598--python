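"""Generative model: rate law, potential wiring, stochastic update,
master-equation propagation, and the deterministic mean-field limit.

The model consists of four pools of ``N`` independently bistable binary
variables.  Two evidence pools (E, E') accumulate visual drive from the two
images; two decision pools (R, R') implement a winner-take-all competition
between the corresponding perceptual hypotheses.  A variable flips on/off
with Poisson rates that depend exponentially and anti-symmetrically on the
activation energy ``Delta_u = u + u0``::

    nu_plus = (nu/2) exp(+Delta_u / 2),   nu_minus = (nu/2) exp(-Delta_u / 2)

with the input-dependent potentials

    u_e  = w_vis f(c)  - w_supp r                       (evidence)
    u_r  = w_exc e - w_inh (e + e') + w_coop r - w_comp r'   (decision)

Feedback suppression (``w_supp``) from a dominant decision pool onto its own
evidence pool drives the system perpetually out of equilibrium and produces
the alternations of binocular rivalry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.linalg

from . import _kernels
from .params import ModelParams, contrast_transfer

__all__ = [
    "RatePair",
    "SystemState",
    "SystemTrajectory",
    "pool_rates",
    "evidence_potentials",
    "decision_potentials",
    "relaxation_constants",
    "step_system",
    "simulate",
    "simulate_meanfield",
    "master_equation_evolve",
    "stationary_distribution",
]

DEFAULT_DT = 5e-4  # s; well below the fastest baseline timescale 1/nu_r = 18 ms


class RatePair(NamedTuple):
    nu_plus: float
    nu_minus: float


class RelaxationConstants(NamedTuple):
    tau: float
    x_inf: float


@dataclass
class SystemState:
    """Active counts of the four pools at one instant."""

    n_e: int
    n_e2: int
    n_r: int
    n_r2: int
    t: float = 0.0

    def validate(self, N: int) -> None:
        for n in (self.n_e, self.n_e2, self.n_r, self.n_r2):
            if not 0 <= n <= N:
                raise ValueError(f"count {n} outside [0, {N}]")


@dataclass
class SystemTrajectory:
    """Uniformly sampled fractional activities of the four pools."""

    times: np.ndarray
    e: np.ndarray
    e_prime: np.ndarray
    r: np.ndarray
    r_prime: np.ndarray
    c: float
    c_prime: float
    dt: float
    seed: int | None = None
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if any(len(a) != n for a in (self.e, self.e_prime, self.r, self.r_prime)):
            raise ValueError("pool arrays must match times in length")

    @property
    def duration(self) -> float:
        return float(self.times[-1])


def pool_rates(delta_u: float, nu_base: float) -> RatePair:
    """Transition rates of one bistable variable at activation energy ``delta_u``.

    Rates vary exponentially and anti-symmetrically, so that
    ``nu_plus * nu_minus = (nu_base / 2)**2`` for any ``delta_u``.
    """
    if nu_base <= 0:
        raise ValueError("nu_base must be > 0")
    if not math.isfinite(delta_u):
        raise ValueError("delta_u must be finite")
    half = 0.5 * nu_base
    return RatePair(half * math.exp(0.5 * delta_u), half * math.exp(-0.5 * delta_u))


def evidence_potentials(c, c2, r, r2, params: ModelParams):
    """Input-dependent potentials of the evidence pools (baseline excluded).

    ``u_e = w_vis f(c) - w_supp r`` and symmetrically for the primed pool;
    the total activation energy entering the rate law is ``u_e + ue0``.
    """
    _check_fraction(r, "r")
    _check_fraction(r2, "r2")
    u_e = params.w_vis * contrast_transfer(c, params.gamma) - params.w_supp * r
    u_e2 = params.w_vis * contrast_transfer(c2, params.gamma) - params.w_supp * r2
    return u_e, u_e2


def decision_potentials(e, e2, r, r2, params: ModelParams):
    """Input-dependent potentials of the decision pools (baseline excluded)."""
    for name, x in (("e", e), ("e2", e2), ("r", r), ("r2", r2)):
        _check_fraction(x, name)
    fwd = params.w_inh * (e + e2)
    u_r = params.w_exc * e - fwd + params.w_coop * r - params.w_comp * r2
    u_r2 = params.w_exc * e2 - fwd + params.w_coop * r2 - params.w_comp * r
    return u_r, u_r2


def relaxation_constants(s: float, nu_base: float, w: float, u0: float) -> RelaxationConstants:
    """Mean-field relaxation time and asymptote for one pool at input ``s``.

    ``tau = 1 / (nu+ + nu-)`` and ``x_inf = nu+ / (nu+ + nu-)``; ``x_inf``
    is sigmoidal in ``s`` with half-activation at ``s = -u0 / w``.
    """
    nu_p, nu_m = pool_rates(w * s + u0, nu_base)
    tot = nu_p + nu_m
    return RelaxationConstants(1.0 / tot, nu_p / tot)


def _check_fraction(x, name: str) -> None:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


def _transition_probability(nu: float, dt: float) -> float:
    return -math.expm1(-nu * dt)


def step_system(
    state: SystemState,
    params: ModelParams,
    c: float,
    c_prime: float,
    dt: float,
    rng: np.random.Generator,
) -> SystemState:
    """One binomial Ehrenfest update of all four pools.

    Per pool, ``Delta n = Binomial(N - n, p+) - Binomial(n, p-)`` with
    ``p = 1 - exp(-nu dt)``, rates recomputed from the pre-step state.  This
    reference implementation is used for validation; long simulations go
    through the compiled kernel in :func:`simulate`.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    N = params.N
    state.validate(N)
    e, e2 = state.n_e / N, state.n_e2 / N
    r, r2 = state.n_r / N, state.n_r2 / N
    u_e, u_e2 = evidence_potentials(c, c_prime, r, r2, params)
    u_r, u_r2 = decision_potentials(e, e2, r, r2, params)
    new = []
    for n, nu_base, du in (
        (state.n_e, params.nu_e, u_e + params.ue0),
        (state.n_e2, params.nu_e, u_e2 + params.ue0),
        (state.n_r, params.nu_r, u_r + params.ur0),
        (state.n_r2, params.nu_r, u_r2 + params.ur0),
    ):
        nu_p, nu_m = pool_rates(np.clip(du, -120.0, 120.0), nu_base)
        up = rng.binomial(N - n, _transition_probability(nu_p, dt)) if n < N else 0
        dn = rng.binomial(n, _transition_probability(nu_m, dt)) if n > 0 else 0
        new.append(n + up - dn)
    return SystemState(*new, t=state.t + dt)


def _initial_side(seed: int) -> bool:
    """Fair coin for which decision pool starts dominant, drawn from the seed."""
    return bool(np.random.default_rng(seed).integers(0, 2))


def simulate(
    params: ModelParams,
    c: float,
    c_prime: float,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    record_every: int = 1,
    initial_state: SystemState | None = None,
) -> SystemTrajectory:
    """Simulate the full stochastic system and return its trajectory.

    The default initial condition is empty evidence pools and one decision
    pool fully active, the side chosen by a fair coin derived from ``seed``;
    trajectories are bit-exactly reproducible for a fixed seed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    I1 = contrast_transfer(c, params.gamma)
    I2 = contrast_transfer(c_prime, params.gamma)
    n_steps = int(round(duration / dt))
    if initial_state is None:
        init = (-1, -1, -1, -1)
    else:
        initial_state.validate(params.N)
        init = (
            initial_state.n_e,
            initial_state.n_e2,
            initial_state.n_r,
            initial_state.n_r2,
        )
    pools = _kernels.sim_trajectory(
        params.N,
        params.nu_e,
        params.nu_r,
        params.ue0,
        params.ur0,
        params.w_vis,
        params.w_exc,
        params.w_inh,
        params.w_comp,
        params.w_coop,
        params.w_supp,
        I1,
        I2,
        dt,
        n_steps,
        record_every,
        seed % (2**32),
        _initial_side(seed),
        *init,
    )
    if not np.all(np.isfinite(pools)):
        raise FloatingPointError("non-finite pool activity encountered")
    times = np.arange(pools.shape[1]) * (dt * record_every)
    return SystemTrajectory(
        times, pools[0], pools[1], pools[2], pools[3], c, c_prime, dt * record_every,
        seed=seed, params=params,
    )


def simulate_meanfield(
    params: ModelParams,
    c: float,
    c_prime: float,
    duration: float,
    dt: float = DEFAULT_DT,
    record_every: int = 1,
    initial_state: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 0.0),
) -> SystemTrajectory:
    """Deterministic N -> infinity limit of :func:`simulate`.

    Integrates the relaxation dynamics of all four coupled fractions with an
    exponential integrator (exact for frozen rates, unconditionally stable).
    At the fitted parameters and equal contrasts the mean-field system is a
    relaxation oscillator with strictly periodic reversals.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    I1 = contrast_transfer(c, params.gamma)
    I2 = contrast_transfer(c_prime, params.gamma)
    n_steps = int(round(duration / dt))
    pools = _kernels.meanfield_trajectory(
        params.nu_e,
        params.nu_r,
        params.ue0,
        params.ur0,
        params.w_vis,
        params.w_exc,
        params.w_inh,
        params.w_comp,
        params.w_coop,
        params.w_supp,
        I1,
        I2,
        dt,
        n_steps,
        record_every,
        *initial_state,
    )
    if np.any(pools < -1e-9) or np.any(pools > 1 + 1e-9):
        raise FloatingPointError(
            "mean-field fraction left [0, 1]; use a smaller dt"
        )
    times = np.arange(pools.shape[1]) * (dt * record_every)
    return SystemTrajectory(
        times, pools[0], pools[1], pools[2], pools[3], c, c_prime, dt * record_every,
        seed=None, params=params,
    )


def _generator_matrix(N: int, nu_plus: float, nu_minus: float) -> np.ndarray:
    """Tridiagonal generator of the Ehrenfest process on states 0..N."""
    n = np.arange(N + 1)
    up = (N - n) * nu_plus  # n -> n+1
    down = n * nu_minus  # n -> n-1
    Q = np.zeros((N + 1, N + 1))
    Q[n[:-1] + 1, n[:-1]] += up[:-1]
    Q[n[1:] - 1, n[1:]] += down[1:]
    Q[n, n] -= up + down
    return Q


def master_equation_evolve(
    N: int,
    nu_plus: float,
    nu_minus: float,
    P0: np.ndarray,
    t: float,
) -> np.ndarray:
    """Exact propagation of the single-pool master equation for time ``t``.

    Computes ``P(t) = expm(Q t) P0`` for the tridiagonal birth-death
    generator with constant rates.  For any initial distribution the result
    converges to Binomial(N, nu+/(nu+ + nu-)).
    """
    if nu_plus < 0 or nu_minus < 0:
        raise ValueError("rates must be >= 0")
    P0 = np.asarray(P0, dtype=float)
    if P0.shape != (N + 1,):
        raise ValueError(f"P0 must have length N + 1 = {N + 1}")
    if abs(P0.sum() - 1.0) > 1e-9 or np.any(P0 < -1e-12):
        raise ValueError("P0 must be a probability distribution")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return P0.copy()
    Q = _generator_matrix(N, nu_plus, nu_minus)
    P = scipy.linalg.expm(Q * t) @ P0
    P = np.clip(P, 0.0, None)
    return P / P.sum()


def stationary_distribution(N: int, nu_plus: float, nu_minus: float) -> np.ndarray:
    """Stationary law of the constant-rate pool: Binomial(N, nu+/(nu+ + nu-))."""
    from scipy.stats import binom

    p = nu_plus / (nu_plus + nu_minus)
    return binom.pmf(np.arange(N + 1), N, p)
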