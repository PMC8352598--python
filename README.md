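# rivalsim

Binocular rivalry as nested attractor dynamics: a simulator and analysis
toolkit for the stochastic alternations of multistable perception.

When the two eyes see incompatible images, phenomenal appearance reverses
at irregular intervals. Across stimuli, observers and modalities these
alternations share quasi-universal statistics: mean dominance durations
follow Levelt's propositions I–IV, duration distributions keep a gamma-like
shape with cV ≈ 0.5–0.6 (the "scaling property"), and successive durations
are positively correlated. `rivalsim` implements a hierarchical,
out-of-equilibrium model that reproduces all three families of facts from
a single mechanism, together with the full statistics pipeline used to
test it against key-press reports.

## Model

Four pools of N = 25 bistable binary variables interact through six
couplings. A variable flips with Poisson rates

    ν± = (ν/2) · exp(±Δu/2),   Δu = u + u₀

Evidence pools E, E′ accumulate visual drive, u_e = w_vis f(c) − w_supp r,
with f(c) = ln(1+c/γ)/ln(1+1/γ); decision pools R, R′ compete
winner-take-all, u_r = w_exc e − w_inh(e+e′) + w_coop r − w_comp r′. The
count of active variables in each pool is an Ehrenfest (birth–death)
process, updated per step by Δn = B(N−n, p₊) − B(n, p₋) with
p± = 1 − exp(−ν± dt). Feedback suppression (w_supp) of the dominant
evidence keeps the system out of equilibrium: dominant evidence
habituates, suppressed evidence recovers, and when the evidence difference
Δe contradicts the current decision beyond a threshold Δrev, the decision
flips. Because Δrev falls with the combined evidence (e+e′)/2, higher
contrast shortens dominance (Levelt IV), and slow fluctuations of the
evidence level produce positive serial correlations that grow with
contrast — a signature that distinguishes this mechanism from
adaptation-based oscillators (implemented for comparison in
`rivalsim.altmodel`, which predicts *negative* same-percept correlations).

## Worked example

```python
from rivalsim import (ModelParams, simulate, extract_dominance,
                      duration_moments, lagged_correlation)

params = ModelParams()                      # fitted constants
traj = simulate(params, c=0.5, c_prime=0.5, duration=300.0, seed=7,
                record_every=10)
series = extract_dominance(traj, burn_in=30.0)
m = duration_moments(series.durations)
print(f"periods: {len(series)}")
print(f"mean duration: {m.mu1:.2f} s   cV: {m.cv:.2f}   gamma1/cV: {m.rel_skew:.2f}")
print(f"lag-1 correlation: {lagged_correlation(series, 1):+.3f}")
```

prints

```
periods: 146
mean duration: 1.82 s   cV: 0.55   gamma1/cV: 2.46
lag-1 correlation: +0.233
```

Five minutes of simulated rivalry at half contrast yield 146 dominance
periods averaging 1.8 s; the coefficient of variation 0.55 sits in the
empirical 0.5–0.6 band, the relative skewness is near the gamma value 2,
and successive durations correlate positively — at full contrast the
correlation is ~0.2, at c = 1/16 it vanishes.

The same analyses run from the shell:

```bash
rivalsim simulate --c 1 --c-prime 1 --duration 60 --seed 1 --out runs/demo
rivalsim grid --periods 300 --seed 1 --out runs/grid
rivalsim fixtures --rho 0.2 --seed 2 --out runs/fixture
rivalsim calibrate --out runs/calib
```

Every command writes a manifest (command, config hash, seed, outputs) and
is bit-exactly reproducible from it.

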