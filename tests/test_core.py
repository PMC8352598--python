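"""Core model: rate law, potentials, stochastic update, master equation,
mean-field limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rivalsim import (
    ModelParams,
    SystemState,
    contrast_transfer,
    master_equation_evolve,
    pool_rates,
    relaxation_constants,
    simulate,
    simulate_meanfield,
    step_system,
)
from rivalsim.core import (
    decision_potentials,
    evidence_potentials,
    stationary_distribution,
)


class TestContrastTransfer:
    @pytest.mark.parametrize(
        "c,expected",
        [(1.0, 1.0), (0.0, 0.0), (1 / 16, 0.2327)],
    )
    def test_values(self, c, expected):
        assert contrast_transfer(c, 0.071) == pytest.approx(expected, abs=5e-4)

    def test_strictly_increasing(self):
        c = np.linspace(0, 1, 101)
        assert np.all(np.diff(contrast_transfer(c, 0.071)) > 0)

    @pytest.mark.parametrize("c", [-0.1, 1.1])
    def test_domain_error(self, c):
        with pytest.raises(ValueError):
            contrast_transfer(c, 0.071)


class TestPoolRates:
    @pytest.mark.parametrize(
        "du,nu,expected",
        [
            (0.0, 1.0, (0.5, 0.5)),
            (2.0, 1.0, (math.e / 2, math.exp(-1) / 2)),
            (-1.65, 1 / 1.95, (0.1124, 0.5851)),
        ],
    )
    def test_values(self, du, nu, expected):
        r = pool_rates(du, nu)
        assert r.nu_plus == pytest.approx(expected[0], rel=1e-3)
        assert r.nu_minus == pytest.approx(expected[1], rel=1e-3)

    @given(du=st.floats(-50, 50), nu=st.floats(1e-3, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_exact(self, du, nu):
        assert pool_rates(du, nu).nu_plus == pool_rates(-du, nu).nu_minus

    @given(du=st.floats(-20, 20), nu=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_rate_product_is_baseline_squared(self, du, nu):
        r = pool_rates(du, nu)
        assert r.nu_plus * r.nu_minus == pytest.approx((nu / 2) ** 2, rel=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pool_rates(float("nan"), 1.0)


class TestPotentials:
    def test_no_drive_no_suppression(self, table_params):
        u_e, _ = evidence_potentials(0.0, 0.0, 0.0, 0.0, table_params)
        assert u_e == 0.0

    def test_full_drive_full_suppression(self, table_params):
        u_e, _ = evidence_potentials(1.0, 1.0, 1.0, 1.0, table_params)
        assert u_e == pytest.approx(1.780 - 2.34, abs=1e-12)

    def test_without_suppression_reduces_to_pure_drive(self, table_params):
        p = table_params.replace(w_supp=0.0)
        u_e, _ = evidence_potentials(0.5, 0.5, 1.0, 1.0, p)
        assert u_e == pytest.approx(p.w_vis * contrast_transfer(0.5, p.gamma))

    def test_decision_zero_state(self, table_params):
        assert decision_potentials(0, 0, 0, 0, table_params) == (0.0, 0.0)

    def test_decision_example(self, table_params):
        u_r, _ = decision_potentials(0.2, 0.05, 0.0, 1.0, table_params)
        assert u_r == pytest.approx(152.2 * 0.2 - 32.10 * 0.25 - 33.4, abs=1e-9)

    def test_decision_swap_symmetry(self, table_params):
        a = decision_potentials(0.3, 0.1, 0.9, 0.2, table_params)
        b = decision_potentials(0.1, 0.3, 0.2, 0.9, table_params)
        assert a == (b[1], b[0])


class TestRelaxation:
    def test_symmetric_rates_give_half(self):
        rc = relaxation_constants(0.0, 1.0, 1.0, 0.0)
        assert rc.x_inf == pytest.approx(0.5)

    @pytest.mark.parametrize("w,u0", [(2.0, -1.0), (10.0, 3.0)])
    def test_half_activation_point(self, w, u0):
        rc = relaxation_constants(-u0 / w, 1.0, w, u0)
        assert rc.x_inf == pytest.approx(0.5)

    def test_tau_longest_at_zero_energy(self):
        taus = [relaxation_constants(s, 1.0, 1.0, 0.0).tau for s in (-3, -1, 0, 1, 3)]
        assert taus[2] == max(taus)
        assert taus[0] < taus[1] < taus[2]


class TestStepSystem:
    def test_counts_stay_in_bounds(self, table_params, rng):
        state = SystemState(0, 0, table_params.N, 0)
        for _ in range(500):
            state = step_system(state, table_params, 1.0, 1.0, 5e-4, rng)
            state.validate(table_params.N)

    def test_one_step_expectation_matches_mean_field(self, decoupled_params, rng):
        """E[dn] = (N-n)p+ - n p- agrees with the relaxation ODE to O(dt^2)."""
        p = decoupled_params
        dt = 1e-3
        n0 = 5
        reps = 40_000
        tot = 0
        for _ in range(reps):
            s = step_system(SystemState(n0, 0, 0, 0), p, 0.0, 0.0, dt, rng)
            tot += s.n_e - n0
        mean_dn = tot / reps
        nu_p, nu_m = pool_rates(p.ue0, p.nu_e)
        expected = ((p.N - n0) * nu_p - n0 * nu_m) * dt
        # MC error ~ sqrt(N p / reps); allow 4 sigma plus the O(dt^2) term
        tol = 4 * math.sqrt(p.N * nu_p * dt / reps) + 10 * dt**2
        assert mean_dn == pytest.approx(expected, abs=tol)

    def test_invalid_dt(self, table_params, rng):
        with pytest.raises(ValueError):
            step_system(SystemState(0, 0, 0, 0), table_params, 1, 1, -1e-3, rng)

    def test_long_run_distribution_is_binomial(self):
        """Stationary occupancy of a constant-rate pool is Binomial(N, x_inf):
        the detailed-balance law of the master equation."""
        p = ModelParams(
            N=8, w_vis=0, w_exc=0, w_inh=0, w_comp=0, w_coop=0, w_supp=0,
            ue0=-0.5, inv_nu_e=0.05,
        )
        tr = simulate(p, 0, 0, 4000.0, dt=1e-3, seed=9, record_every=50)
        n = np.rint(tr.e[tr.times > 2.0] * p.N).astype(int)
        emp = np.bincount(n, minlength=p.N + 1) / len(n)
        ref = stationary_distribution(p.N, *pool_rates(p.ue0, p.nu_e))
        assert 0.5 * np.abs(emp - ref).sum() < 0.01


class TestMasterEquation:
    def test_zero_time_is_identity(self):
        P0 = np.zeros(6)
        P0[2] = 1.0
        np.testing.assert_allclose(master_equation_evolve(5, 1.0, 2.0, P0, 0.0), P0)

    def test_long_time_limit_is_binomial(self):
        N, nup, num = 7, 0.8, 1.7
        P0 = np.zeros(N + 1)
        P0[N] = 1.0
        P = master_equation_evolve(N, nup, num, P0, 50.0)
        assert abs(P.sum() - 1) < 1e-12
        ref = stationary_distribution(N, nup, num)
        assert 0.5 * np.abs(P - ref).sum() < 1e-8

    def test_agrees_with_monte_carlo(self, rng):
        """Finite-time law matches sampled binomial-update dynamics (N=3)."""
        N, nup, num, t = 3, 1.2, 0.7, 0.8
        P0 = np.zeros(N + 1)
        P0[0] = 1.0
        P = master_equation_evolve(N, nup, num, P0, t)
        dt = 1e-3
        steps = int(t / dt)
        reps = 200_000
        n = np.zeros(reps, dtype=int)
        p_up = -np.expm1(-nup * dt)
        p_dn = -np.expm1(-num * dt)
        for _ in range(steps):
            n = n + rng.binomial(N - n, p_up) - rng.binomial(n, p_dn)
        emp = np.bincount(n, minlength=N + 1) / reps
        assert 0.5 * np.abs(emp - P).sum() < 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            master_equation_evolve(3, -1.0, 1.0, np.ones(4) / 4, 1.0)


class TestSimulate:
    def test_same_seed_identical(self, table_params):
        a = simulate(table_params, 1, 1, 5.0, seed=7)
        b = simulate(table_params, 1, 1, 5.0, seed=7)
        np.testing.assert_array_equal(a.r, b.r)
        np.testing.assert_array_equal(a.e, b.e)

    def test_fractions_bounded(self, table_params):
        t = simulate(table_params, 1, 0.25, 10.0, seed=3)
        for arr in (t.e, t.e_prime, t.r, t.r_prime):
            assert arr.min() >= 0 and arr.max() <= 1

    def test_alternation_at_equal_contrast(self, table_params):
        from rivalsim import extract_dominance

        t = simulate(table_params, 1, 1, 60.0, seed=5, record_every=10)
        s = extract_dominance(t, burn_in=5.0)
        assert len(s) >= 10
        assert set(np.unique(s.labels)) == {-1, 1}
        assert np.all(s.labels[1:] != s.labels[:-1])

    def test_strong_bias_gives_high_predominance(self, table_params):
        """A zero-contrast competitor is dominated nearly all the time; the
        undriven percept intrudes only briefly (its undriven evidence baseline
        still occasionally contradicts the suppressed driven evidence)."""
        preds = []
        for seed in (11, 12, 13):
            t = simulate(table_params, 1.0, 0.0, 40.0, seed=seed, record_every=10)
            sel = t.times > 10.0
            preds.append((t.r[sel] > t.r_prime[sel]).mean())
        assert np.mean(preds) > 0.85

    def test_contrast_swap_symmetry(self, table_params):
        """Swapping (c, c') mirrors predominance at the distribution level."""
        pred = []
        for seed in range(6):
            t = simulate(table_params, 1.0, 0.25, 60.0, seed=20 + seed, record_every=20)
            sel = t.times > 30.0
            pred.append((t.r[sel] > t.r_prime[sel]).mean())
        pred_swap = []
        for seed in range(6):
            t = simulate(table_params, 0.25, 1.0, 60.0, seed=40 + seed, record_every=20)
            sel = t.times > 30.0
            pred_swap.append((t.r_prime[sel] > t.r[sel]).mean())
        assert np.mean(pred) == pytest.approx(np.mean(pred_swap), abs=0.12)

    def test_fluctuations_shrink_with_pool_size(self, table_params):
        """Across-trajectory variance of e(t) falls roughly as 1/N."""
        def spread(N, seeds):
            p = table_params.replace(N=N)
            vals = [
                simulate(
                    p, 0.5, 0.5, 1.0, seed=s, record_every=100,
                    initial_state=SystemState(0, 0, N, 0),
                ).e[-1]
                for s in seeds
            ]
            return np.var(vals)

        v25 = spread(25, range(60))
        v200 = spread(200, range(60, 120))
        assert v200 < v25 / 2.5


class TestMeanField:
    def test_single_pool_matches_analytic_relaxation(self, decoupled_params):
        """Uncoupled pool under constant input: x(t) = x_inf + (x0-x_inf)e^-t/tau."""
        p = decoupled_params
        tr = simulate_meanfield(p, 0, 0, 2.0, dt=5e-4, initial_state=(0, 0, 1, 0))
        rc = relaxation_constants(0.0, p.nu_e, 1.0, p.ue0)
        expected = rc.x_inf * (1 - np.exp(-tr.times / rc.tau))
        np.testing.assert_allclose(tr.e, expected, atol=1e-6)

    def test_relaxation_oscillator_at_equal_contrast(self, table_params):
        tr = simulate_meanfield(table_params, 0.5, 0.5, 60.0)
        d = tr.r - tr.r_prime
        crossings = np.flatnonzero(np.diff(np.sign(d)) != 0)
        assert len(crossings) >= 10
        periods = np.diff(crossings[2:]) * tr.dt
        assert periods.std() / periods.mean() < 1e-3  # strictly periodic

    def test_periods_start_and_end_at_equal_evidence(self, table_params):
        tr = simulate_meanfield(table_params, 0.5, 0.5, 60.0)
        d = tr.r - tr.r_prime
        crossings = np.flatnonzero(np.diff(np.sign(d)) != 0)[2:]
        e_at = tr.e[crossings]
        e2_at = tr.e_prime[crossings]
        # at each reversal one evidence is at the start level, the other at
        # the end level; consecutive reversals mirror them
        np.testing.assert_allclose(e_at[:-1], e2_at[1:], atol=5e-3)

    def test_ensemble_mean_tracks_mean_field(self, table_params):
        """Stochastic ensemble mean of e(t) follows the deterministic limit
        between reversals (identical initial conditions, no reversal window)."""
        init = (0.0, 0.0, 1.0, 0.0)
        mf = simulate_meanfield(table_params, 0.5, 0.5, 1.0, initial_state=init,
                                record_every=200)
        from rivalsim.core import SystemState

        runs = []
        for seed in range(150):
            t = simulate(
                table_params, 0.5, 0.5, 1.0, seed=seed, record_every=200,
                initial_state=SystemState(0, 0, table_params.N, 0),
            )
            runs.append(t.e)
        runs = np.array(runs)
        mean = runs.mean(axis=0)
        sem = runs.std(axis=0) / np.sqrt(len(runs))
        ok = np.abs(mean - mf.e) <= 3 * np.maximum(sem, 1e-4)
        assert ok.mean() > 0.9
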