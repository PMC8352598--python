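# Methods

## Model

`rivalsim` simulates binocular rivalry as a hierarchy of interacting
Ehrenfest (birth–death) processes. Four pools of `N` bistable binary
variables represent monocular evidence (E, E′) and the two competing
perceptual hypotheses (R, R′). Each variable flips between its on- and
off-state with Poisson rates that depend exponentially and
anti-symmetrically on an activation energy Δu = u + u₀:

    ν± = (ν/2) exp(±Δu/2)

so that ν₊ν₋ = (ν/2)² for any input. The input-dependent potentials wire
the hierarchy together:

    u_e = w_vis f(c) − w_supp r                                  (evidence)
    u_r = w_exc e − w_inh (e + e′) + w_coop r − w_comp r′         (decision)

with f(c) = ln(1 + c/γ)/ln(1 + 1/γ) a compressive contrast transfer.
Evidence pools integrate visual drive slowly (baseline 1/ν_e ≈ 2 s);
decision pools implement a fast winner-take-all competition (1/ν_r = 18 ms)
through self-cooperation and cross-competition. The one deliberately
destabilizing element is feedback suppression `w_supp`: the dominant
decision pool inhibits its own supporting evidence, so dominant evidence
habituates while suppressed evidence recovers, until the evidence
difference Δe = e − e′ contradicts the current decision strongly enough to
destabilize it. The system therefore never reaches equilibrium and
alternates perpetually.

In discrete time, each pool count is updated per step as

    Δn = Binomial(N − n, p₊) − Binomial(n, p₋),  p± = 1 − exp(−ν± dt)

The exponential waiting-time mapping (rather than p = ν dt) matters:
decision-pool rates reach ~10⁶ Hz transiently during reversals, and the
mapping keeps probabilities valid at any dt while agreeing with ν dt to
first order. For constant rates the count distribution solves the
birth–death master equation exactly; `master_equation_evolve` propagates
that equation with a matrix exponential of the tridiagonal generator and is
used as the oracle in tests (stationary law Binomial(N, ν₊/(ν₊+ν₋))).

### Parameters

All twelve constants live in `ModelParams` (defaults are the fitted values
for human observers): pool size N = 25; inverse baseline rates 1/ν_e =
1.95 s, 1/ν_r = 0.018 s; baseline potentials ue0 = −1.65, ur0 = −4.94
(dimensionless activation energies); couplings w_vis = 1.780, w_exc =
152.2, w_inh = 32.10, w_comp = 33.4, w_coop = 15.21, w_supp = 2.34;
contrast nonlinearity γ = 0.071. Simulation controls: dt = 0.5 ms (well
below 1/ν_r; halving dt leaves the summary statistics unchanged within
sampling error), burn-in 30 s, initial condition e = e′ = 0 with one
decision pool fully active (side drawn by a fair coin from the seed).

### Mean-field limit

For N → ∞ each fraction follows d⟨x⟩/dt = (1−⟨x⟩)ν₊ − ⟨x⟩ν₋, relaxing
with τ = 1/(ν₊+ν₋) toward x∞ = ν₊/(ν₊+ν₋). `simulate_meanfield`
integrates the four coupled fractions with an exponential integrator: per
step the rates are frozen and the exact linear relaxation applied. The
scheme is unconditionally stable — an explicit Runge–Kutta step at dt =
0.5 ms diverges when decision rates explode during reversals — and is exact
for a single pool under constant input, which the tests exploit (agreement
with the closed-form relaxation to 1e−6). At the default parameters and
equal contrasts the mean-field system is a strictly periodic relaxation
oscillator whose dominance periods start and end at mirrored evidence
levels.

`reversal_threshold_scan` measures the deterministic reversal threshold
Δrev(ē): evidence fractions are frozen at mean ē with bias Δe against the
dominant decision state, and the smallest destabilizing Δe is bisected.
Below ē ≈ 0.14 no admissible bias flips the state (threshold reported as
∞), so the default grid spans ē ∈ [0.15, 0.35], the operating range of the
fitted model. Within it Δrev falls monotonically and near-linearly; its
slope magnitude follows 2|w_exc − 2 w_inh|/w_exc, i.e. it is set jointly by
the feedforward projections (removing inhibition steepens it; strong
inhibition reverses its sign because the winner's stability becomes the
binding constraint).

## Dominance statistics

Percepts are read from the decision pools with a hysteresis state machine:
a percept is established when its fraction rises above 1 − h while the
rival falls below h (h = 0.2 by default), and the reversal instant is the
zero crossing of r − r′ between two established states. Transitions take a
few milliseconds at the default parameters, so durations are insensitive
to the convention (mean changes < 2% between h = 0.1 and 0.2). Periods
beginning before the burn-in are dropped.

Per condition and grid cell the package computes: central moments μ₁, μ₂
(variance), μ₃; cV = √μ₂/μ₁; relative skewness γ₁/cV = μ₃μ₁/μ₂² (exactly 2
for any gamma distribution); lagged Pearson correlations cc_k over period
pairs (T_i, T_{i+k}); a burstiness index BI(k) — the z-score of the cV of
k-period sliding-window means against order-shuffled surrogates; octile
conditional expectations ⟨T±n⟩ and ⟨ē±n⟩; and the evidence bias |e − e′|
and mean (e + e′)/2 sampled at reversal instants.

`run_contrast_grid` simulates the conditions c ≥ c′ of a contrast grid
(mirror conditions are statistically identical) and keys every period by
(c_dom, c_sup) — the contrast feeding the dominant percept first — which
populates all ordered cells, exactly as symmetric experimental conditions
are merged. Lagged pairs are assigned to the cell of the leading period
and never cross condition boundaries.

## Observer data

The key-press dialect is a CSV with columns
`observer,block,c_left,c_right,t,state` (state ∈ L/R/N at 60 Hz). Parsing
takes contiguous single-key runs within the final 90 s of each 120 s
block; `N` samples (mixed percepts) separate periods, and runs clipped by
either window edge are discarded — a truncated duration is not a dominance
duration. Preprocessing removes the mean linear trend per block by OLS on
the period index (periods, not clock time, are the analysis unit) while
preserving the block mean, and observers are made comparable by rescaling
with grand-mean/observer-mean (2.5 s all-condition average).

The synthetic observer draws gamma durations (default shape 1/0.55² ≈ 3.3,
the midpoint of the empirical cV band 0.5–0.6; mean 2.5 s) modulated
multiplicatively by a mean-one log-normal AR(1) process (decay 0.7 per
period). The latent variance is solved so the lag-1 duration correlation
equals the requested value; correlations then decay geometrically with
lag, which mimics the slow-fluctuation origin of serial dependence in the
model. It emulates clear-visibility reports with exponential mixed-percept
gaps (25% of time by default) split into 120 s blocks. It does not emulate
eye-movement artifacts, piecemeal rivalry, attention lapses, or
duration-dependent report latencies, so parsing-pipeline tests validate
bookkeeping and estimator calibration, not perceptual realism.
`sem_calibration` measures the sampling error of every statistic on iid
gamma sets (for 1000-sample sets: ~2% relative SEM of the mean, ~2.5% for
cV, ~11% for γ₁/cV, SD of cc1 ≈ 0.032).

## Fisher-information capture

The capture claim — pools of N = 25 bistable variables with coupling
w = 2.5 retain ≥ 90% of the information an ideal observer extracts from a
sequence of noisy samples — is evaluated with a protocol reconstructed by
this package (the original derivation is not available in the source
text). Each of m = 20 samples s ~ N(μ, σ) drives a fresh, initially
inactive *opponent pair* of pools (couplings +w and −w, mirroring how
conflicting evidence excites one evidence pool and counts against the
other) for one baseline relaxation time; the readout is the summed
differential count. Fisher information about μ is estimated as
(d⟨n⟩/dμ)²/Var(n) on a grid of means and divided by the ideal m/σ².
Counts are sampled exactly: a variable starting inactive under constant
rates is active after time T with probability x∞(1 − e^{−T/τ}).

The default input SD is 0.8, keeping the per-sample log-odds swing w·σ ≈ 2
within the sensitive range of the activation sigmoid; capture degrades
through saturation for much wider inputs and through channel noise
(relative to the shrinking ideal information) for much narrower ones. A
single pool read out only through its final count cannot express the
claim: geometric forgetting and binomial channel noise cap it near 30%
under any (σ, step) setting we scanned, which is why the opponent-pair
readout — the architecture the model itself uses — defines the protocol.
At the defaults the measured capture is ~92–93% (N = 25), ~79% at N = 4,
and ~94% at N = 400.

## Alternative model

For comparison, `altmodel` implements the classic competition + adaptation
+ colored-noise oscillator: two rate units with logistic activation
(width κ = 0.1), mutual inhibition β = 10, activity time constant τ_r =
50 ms, slow adaptation (strength φ_a, time constant τ_a read in seconds),
and Ornstein–Uhlenbeck noise (τ_n = 500 ms) whose stationary SD, like the
input, is a power law of contrast (I = b_I c^{k_I}, σ = b_σ c^{k_σ}).
Integration is Euler for the deterministic part with the exact OU update
(exponential decay plus matched Gaussian increment), making the noise
statistics dt-independent. Defaults are the published best-fit values
(φ_a = 18.39, τ_a = 22.78 s, b_I = 2.92, k_I = 1.52, b_σ = 0.19,
k_σ = 0.57). Free parameters are fitted with seeded differential evolution
within the published exploration ranges, minimizing the mean relative
error over ⟨T⟩, cV, γ₁ and cc1 at equal-contrast conditions (the 1,1,1,1/4
weighted error is reported alongside).

The scientific point of the module is a sign dichotomy: adaptation is an
opponent process, so it produces *negative* correlations between
same-percept durations (cc₂ < 0 at the fitted parameters, ≈ −0.03 at
c = c′ = 1), whereas feedback suppression in the hierarchical model makes
correlations positive at all lags (cc₂ ≈ +0.09 at c = c′ = 1).

## Fitting

`fit_error` compares four observables between a model grid and targets:
the ⟨T⟩ matrix, the cV matrix, and scalar γ₁/cV and cc1 (grid averages).
Per observable δ = mean|X_mod − X_exp| / mean(X_exp); Efit is the weighted
mean with weights (1, 1, 1, 1/4), de-emphasizing the noisy correlation.
Model evaluations are stochastic, so every search uses common random
numbers (a fixed simulation seed per evaluation): two evaluations at the
same parameters are bit-identical, making comparisons noise-free.

`random_restart_search` is a simultaneous-perturbation (SPSA) descent with
geometrically decaying steps from random starting points (log-uniform in
the bounds for positive parameters); the exact descent rule is this
package's choice, as only "stochastic gradient descent" is named in the
source. `sensitivity_scan` evaluates Efit on a grid around an optimum and
fits a parabola, reporting curvature with a 95% CI and the vertex;
`solution_manifold_pca` standardizes the terminal parameter vectors of
many runs and reports the SVD explained-variance spectrum — a low
component count signals few effective degrees of freedom. Desk-scale
defaults (3-level grids, ~300 periods per evaluation, a handful of runs)
keep a search in minutes; a full 5×5, many-hundred-run campaign is a
matter of raising the same arguments.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 1000 periods per merged cell
for the 5×5 grid (≈ 25 000 periods, ≈ 7 h of simulated rivalry), 3000–5000
periods per equal-contrast condition, 2500 calibration replicates, and
16 000 trials per Fisher grid point. Compiled (numba) kernels advance the
four pools at ≈ 10⁷ steps/s, so the full grid takes well under a minute.
Seeds: every public entry point takes a seed; per-condition seeds are
derived through `numpy.random.SeedSequence` and recorded, and identical
seeds reproduce trajectories bit-exactly.

Degenerate inputs are handled explicitly: zero-variance duration samples
give cc = NaN with a warning; conditions that produce no reversal within
the wall limit yield flagged cells rather than errors; unreachable
reversal thresholds are reported as ∞.

## Known limitations

- At the lowest contrasts the fitted model's reversals are
  fluctuation-driven escapes; duration distributions become heavier-tailed
  than gamma (γ₁/cV rises to ~3 at c = 1/16, diagonal average ~2.6–2.7),
  and the mean evidence bias at reversals in the lowest-contrast cell
  (~0.23) sits slightly above the deterministic threshold band (~0.20).
  Both are properties of the mechanism as reconstructed here, reported as
  computed.
- The spiking-network realization of a bistable assembly is out of scope;
  the binary-variable idealization is the modeling primitive.
- One local visual-field site is modeled: no piecemeal rivalry, traveling
  waves, sensory memory, or attentional modulation.
- Observer-data tooling expects the package's CSV dialect; no display or
  eye-tracking hardware interfaces are provided.
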