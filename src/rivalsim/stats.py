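"""Dominance-duration statistics.

Turns trajectories (stochastic or mean-field) into sequences of dominance
periods and computes the statistics used to characterize binocular rivalry:
central moments and shape measures of the duration distribution, lagged
serial correlations, a burstiness index, conditional-expectation (octile)
tables, evidence state at reversals, the deterministic reversal-threshold
curve, and full contrast-grid summaries.

Conventions
-----------
A percept is considered established when its decision pool's fraction rises
above ``1 - hysteresis`` while the rival pool falls below ``hysteresis``;
the reversal instant is the zero crossing of ``r - r'`` between two such
established states.  Decision transitions at the fitted parameters take a
few milliseconds, so dominance durations are insensitive to the exact
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .core import DEFAULT_DT, SystemTrajectory
from .params import ModelParams, contrast_transfer

__all__ = [
    "DominanceSeries",
    "SummaryStats",
    "GridResult",
    "extract_dominance",
    "periods_from_difference",
    "duration_moments",
    "lagged_correlation",
    "burstiness",
    "conditional_octiles",
    "reversal_state_stats",
    "reversal_threshold_scan",
    "run_contrast_grid",
    "fisher_info_ratio",
    "summarize_durations",
]

DEFAULT_CONTRAST_LEVELS = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0)


@dataclass
class DominanceSeries:
    """Ordered dominance periods of one condition.

    ``labels`` are +1/-1 for the two percepts (for observer data +1 is the
    left-eye image).  ``extras`` may carry per-period evidence samples
    (``e_end``, ``e2_end``: evidence fractions at the reversal terminating
    each period) for model-derived series.
    """

    labels: np.ndarray
    onsets: np.ndarray
    durations: np.ndarray
    condition: tuple | None = None
    source: str = "model"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.labels) == len(self.onsets) == len(self.durations)):
            raise ValueError("labels, onsets, durations must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be > 0")

    def __len__(self) -> int:
        return len(self.durations)


class Moments(NamedTuple):
    mu1: float
    mu2: float
    mu3: float
    cv: float
    rel_skew: float


@dataclass
class SummaryStats:
    """Duration statistics of one condition / grid cell."""

    n_periods: int
    mu1: float
    mu2: float
    mu3: float
    cv: float
    rel_skew: float
    cc: dict = field(default_factory=dict)  # lag -> correlation
    bi: dict = field(default_factory=dict)  # window size -> burstiness index
    mean_de_rev: float = np.nan
    mean_ebar_rev: float = np.nan
    flagged: bool = False


@dataclass
class GridResult:
    """Per-cell summary statistics over a contrast grid.

    Cells are keyed ``(c_dom, c_sup)``: the contrast driving the dominant
    percept and the contrast driving the suppressed one.  Simulating the
    conditions with ``c >= c'`` covers all ordered cells because each period
    is keyed by which percept was dominant (mirror conditions pooled).
    """

    levels: tuple
    cells: dict
    target_periods: int
    seed: int
    dt: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cd, cs), s in sorted(self.cells.items()):
            rows.append(
                dict(
                    c_dom=cd,
                    c_sup=cs,
                    n=s.n_periods,
                    mu1=s.mu1,
                    cv=s.cv,
                    rel_skew=s.rel_skew,
                    cc1=s.cc.get(1, np.nan),
                    cc2=s.cc.get(2, np.nan),
                    mean_de_rev=s.mean_de_rev,
                    mean_ebar_rev=s.mean_ebar_rev,
                    flagged=s.flagged,
                )
            )
        return pd.DataFrame(rows)

    def cell_matrix(self, attr: str) -> np.ndarray:
        """(len(levels), len(levels)) matrix of one statistic, [i, j] being
        the cell with c_dom = levels[i], c_sup = levels[j]."""
        L = len(self.levels)
        out = np.full((L, L), np.nan)
        for i, cd in enumerate(self.levels):
            for j, cs in enumerate(self.levels):
                cell = self.cells.get((cd, cs))
                if cell is None or cell.flagged:
                    continue
                if attr.startswith("cc"):
                    out[i, j] = cell.cc.get(int(attr[2:]), np.nan)
                else:
                    out[i, j] = getattr(cell, attr)
        return out


# ---------------------------------------------------------------------
# period extraction


def periods_from_difference(
    times: np.ndarray,
    d: np.ndarray,
    enter: float = 0.6,
    burn_in: float = 0.0,
    aux: dict | None = None,
):
    """Hysteresis extraction of dominance periods from a difference signal.

    A percept is confirmed when ``d`` exceeds ``+enter`` (label +1) or falls
    below ``-enter`` (label -1); the reversal instant is the last zero
    crossing of ``d`` before the new confirmation, linearly interpolated
    between samples.  Periods whose onset precedes ``burn_in`` are dropped.

    Returns (labels, onsets, durations, aux_at_end) where ``aux_at_end``
    maps each key of ``aux`` (arrays aligned with ``times``) to its value at
    the reversal terminating each period.
    """
    d = np.asarray(d, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(d) != len(times):
        raise ValueError("times and difference signal must have equal length")
    conf = np.zeros(len(d), dtype=np.int8)
    conf[d >= enter] = 1
    conf[d <= -enter] = -1
    return _extract_two_sided(times, d, conf, burn_in, aux=aux)


def extract_dominance(
    traj: SystemTrajectory,
    hysteresis: float = 0.2,
    burn_in: float = 0.0,
) -> DominanceSeries:
    """Extract the dominance series from a simulated trajectory.

    The percept is the decision pool whose fraction last rose above
    ``1 - hysteresis`` while the rival fell below ``hysteresis``; reversal
    instants are zero crossings of ``r - r'`` between such states.  A
    trajectory with no completed period yields an empty series.
    """
    if not 0 < hysteresis < 0.5:
        raise ValueError("hysteresis must be in (0, 0.5)")
    r, r2 = traj.r, traj.r_prime
    hi, lo = 1.0 - hysteresis, hysteresis
    conf = np.zeros(len(r), dtype=np.int8)
    conf[(r >= hi) & (r2 <= lo)] = 1
    conf[(r2 >= hi) & (r <= lo)] = -1
    # reuse the difference machinery with a synthetic confirmation signal:
    # feed d = r - r' but gate confirmations through the two-sided rule by
    # mapping confirmed samples onto +-1 thresholds
    labels, onsets, durations, aux_end = _extract_two_sided(
        traj.times,
        r - r2,
        conf,
        burn_in,
        aux={"e": traj.e, "e2": traj.e_prime},
    )
    return DominanceSeries(
        labels,
        onsets,
        durations,
        condition=(traj.c, traj.c_prime),
        source="model",
        extras={"e_end": aux_end["e"], "e2_end": aux_end["e2"]},
    )


def _extract_two_sided(times, d, conf, burn_in, aux=None):
    """Shared walk over confirmation samples and zero crossings of ``d``."""
    nz = np.flatnonzero(conf)
    aux = aux or {}
    empty = (np.array([], int), np.array([]), np.array([]), {k: np.array([]) for k in aux})
    if len(nz) == 0:
        return empty
    states = conf[nz]
    change_pos = np.flatnonzero(np.diff(states) != 0) + 1
    if len(change_pos) < 2:
        return empty
    sgn = np.sign(d)
    sgn[sgn == 0] = 1
    cross_idx = np.flatnonzero(np.diff(sgn) != 0)
    rev_times, rev_idx, rev_labels = [], [], []
    for pos in change_pos:
        i_conf = nz[pos]
        i_prev = nz[pos - 1]
        cand = cross_idx[(cross_idx >= i_prev) & (cross_idx < i_conf)]
        if len(cand) == 0:
            continue
        i = cand[-1]
        t0, t1 = times[i], times[i + 1]
        d0, d1 = d[i], d[i + 1]
        frac = d0 / (d0 - d1) if d0 != d1 else 0.5
        rev_idx.append(i + 1)
        rev_times.append(t0 + frac * (t1 - t0))
        rev_labels.append(states[pos - 1])
    labels, onsets, durations, ends = [], [], [], []
    for k in range(1, len(rev_times)):
        onset = rev_times[k - 1]
        if onset < burn_in:
            continue
        labels.append(rev_labels[k])
        onsets.append(onset)
        durations.append(rev_times[k] - rev_times[k - 1])
        ends.append(rev_idx[k])
    ends = np.asarray(ends, dtype=int)
    aux_end = {k: np.asarray(v)[ends] if len(ends) else np.array([]) for k, v in aux.items()}
    return np.asarray(labels), np.asarray(onsets), np.asarray(durations), aux_end


# ---------------------------------------------------------------------
# scalar statistics


def duration_moments(durations) -> Moments:
    """Central moments and shape measures of a duration sample.

    mu2 is the variance <T^2> - <T>^2 and mu3 the third central moment;
    cV = sqrt(mu2)/mu1 and the relative skewness gamma1/cV = mu3*mu1/mu2^2
    (exactly 2 for any gamma distribution, regardless of shape).
    """
    d = np.asarray(durations, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 durations")
    mu1 = d.mean()
    mu2 = d.var()
    mu3 = ((d - mu1) ** 3).mean()
    cv = np.sqrt(mu2) / mu1
    rel_skew = mu3 * mu1 / mu2**2 if mu2 > 0 else np.nan
    return Moments(mu1, mu2, mu3, cv, rel_skew)


def lagged_correlation(series, lag: int = 1, first_mask=None) -> float:
    """Pearson correlation of period pairs ``(T_i, T_{i+lag})``.

    For a strictly alternating series, lag 1 pairs opposite percepts and
    lag 2 pairs the same percept.  ``first_mask`` restricts pairs to those
    whose *first* period satisfies the mask (used to key pairs by the
    dominant-eye contrast of the leading period).
    """
    d = series.durations if isinstance(series, DominanceSeries) else np.asarray(series, float)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if len(d) < lag + 2:
        raise ValueError(f"need at least lag + 2 = {lag + 2} periods")
    first = np.arange(len(d) - lag)
    if first_mask is not None:
        first = first[np.asarray(first_mask)[: len(d) - lag]]
    if len(first) < 3:
        return np.nan
    x, y = d[first], d[first + lag]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in lagged pairs; correlation undefined")
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _window_means(d: np.ndarray, k: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(d)))
    return (c[k:] - c[:-k]) / k


def burstiness(
    series,
    k_range: Iterable[int] = range(2, 17),
    n_shuffle: int = 1000,
    seed: int = 0,
) -> dict:
    """Burstiness index BI(k): z-score of the variability of k-period window
    means against order-shuffled surrogates.

    All contiguous windows of k successive periods are used; shuffling
    permutes the period order (destroying serial structure while preserving
    the marginal distribution).
    """
    d = series.durations if isinstance(series, DominanceSeries) else np.asarray(series, float)
    k_range = list(k_range)
    if len(d) < max(k_range) + 2:
        raise ValueError("not enough periods for the largest window")
    if n_shuffle < 100:
        warnings.warn("n_shuffle < 100 gives a noisy burstiness z-score")
    rng = np.random.default_rng(seed)
    shuffles = np.array([rng.permutation(d) for _ in range(n_shuffle)])
    out = {}
    for k in k_range:
        wm = _window_means(d, k)
        cv = wm.std() / wm.mean()
        sh_cv = np.empty(n_shuffle)
        for i in range(n_shuffle):
            wms = _window_means(shuffles[i], k)
            sh_cv[i] = wms.std() / wms.mean()
        sd = sh_cv.std()
        out[k] = (cv - sh_cv.mean()) / sd if sd > 0 else np.nan
    return out


def conditional_octiles(series: DominanceSeries, max_lag: int = 4, n_groups: int = 8):
    """Conditional expectations of duration and evidence mean by octile.

    Periods ``T_0`` are ranked and split into ``n_groups`` quantile groups
    (returned from longest to shortest).  For each group, the mean duration
    of periods at lags -max_lag..+max_lag and the mean evidence activity
    ``(e + e')/2`` sampled at the end of each period are reported, both
    normalized by their overall averages.
    """
    d = series.durations
    if "e_end" not in series.extras or "e2_end" not in series.extras:
        raise ValueError("series lacks evidence samples (e_end/e2_end)")
    e_end = np.asarray(series.extras["e_end"], float)
    e2_end = np.asarray(series.extras["e2_end"], float)
    if len(e_end) != len(d) or len(e2_end) != len(d):
        raise ValueError("evidence samples misaligned with durations")
    if len(d) < n_groups * (2 * max_lag + 1):
        raise ValueError("too few periods for octile analysis")
    ebar = 0.5 * (e_end + e2_end)
    lags = np.arange(-max_lag, max_lag + 1)
    valid = np.arange(max_lag, len(d) - max_lag)
    order = np.argsort(d[valid])[::-1]  # longest first
    groups = np.array_split(order, n_groups)
    T_tab = np.empty((n_groups, len(lags)))
    e_tab = np.empty((n_groups, len(lags)))
    for g, idx in enumerate(groups):
        centers = valid[idx]
        for j, lag in enumerate(lags):
            T_tab[g, j] = d[centers + lag].mean()
            e_tab[g, j] = ebar[centers + lag].mean()
    return {
        "lags": lags,
        "T": T_tab / d.mean(),
        "ebar": e_tab / ebar.mean(),
        "T0": np.array([d[valid[idx]].mean() for idx in groups]),
    }


def reversal_state_stats(traj: SystemTrajectory, series: DominanceSeries):
    """Evidence bias and mean at reversal instants.

    Samples ``de = |e - e'|`` and ``ebar = (e + e')/2`` at each reversal
    (period end) of ``series`` and returns ``(mean_de, mean_ebar, samples)``
    where samples is a (n, 2) array of (de, ebar) pairs.
    """
    if "e_end" in series.extras and len(series.extras["e_end"]) == len(series):
        e = np.asarray(series.extras["e_end"], float)
        e2 = np.asarray(series.extras["e2_end"], float)
    else:
        ends = series.onsets + series.durations
        idx = np.searchsorted(traj.times, ends)
        idx = np.clip(idx, 0, len(traj.times) - 1)
        e = traj.e[idx]
        e2 = traj.e_prime[idx]
    if len(e) == 0:
        return np.nan, np.nan, np.empty((0, 2))
    de = np.abs(e - e2)
    ebar = 0.5 * (e + e2)
    return float(de.mean()), float(ebar.mean()), np.column_stack([de, ebar])


# ---------------------------------------------------------------------
# mean-field reversal threshold


def reversal_threshold_scan(
    params: ModelParams,
    ebar_grid=None,
    dt: float = 1e-4,
    t_max: float = 10.0,
    tol: float = 1e-4,
):
    """Deterministic reversal threshold Delta_rev as a function of mean
    evidence ebar = (e + e')/2.

    For each ebar the decision mean-field starts in the state contradicted
    by an evidence bias Delta_e (e = ebar + Delta_e/2 favoring the inactive
    pool) and the smallest destabilizing Delta_e is found by bisection.  If
    no bias up to the admissible maximum flips the state, infinity is
    reported.  At the fitted parameters the curve decreases monotonically:
    feedforward excitation and inhibition jointly lower the threshold as
    combined evidence grows.
    """
    if ebar_grid is None:
        ebar_grid = np.linspace(0.15, 0.35, 9)
    ebar_grid = np.asarray(ebar_grid, dtype=float)
    out = np.empty_like(ebar_grid)
    for i, ebar in enumerate(ebar_grid):
        cap = min(1.0, 2 * ebar, 2 * (1 - ebar))
        flip_at_cap = _kernels.decision_flip(
            params.nu_r, params.ur0, params.w_exc, params.w_inh,
            params.w_comp, params.w_coop,
            ebar + cap / 2, ebar - cap / 2, dt, t_max,
        )
        if flip_at_cap < 0:
            out[i] = np.inf
            continue
        lo, hi = 0.0, cap
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            t_flip = _kernels.decision_flip(
                params.nu_r, params.ur0, params.w_exc, params.w_inh,
                params.w_comp, params.w_coop,
                ebar + mid / 2, ebar - mid / 2, dt, t_max,
            )
            if t_flip > 0:
                hi = mid
            else:
                lo = mid
        out[i] = hi
    return ebar_grid, out


# ---------------------------------------------------------------------
# contrast grid


def summarize_durations(
    durations,
    cc_lags: Sequence[int] = (1, 2),
    first_mask=None,
    full_durations=None,
    de=None,
    ebar=None,
    flagged: bool = False,
) -> SummaryStats:
    """Build a SummaryStats record from a duration sample.

    When the sample is a sub-population of a longer alternating sequence
    (grid cells), pass the full sequence plus ``first_mask`` so that lagged
    pairs are formed in true sequence order.
    """
    mom = duration_moments(durations)
    cc = {}
    seq = full_durations if full_durations is not None else np.asarray(durations, float)
    for k in cc_lags:
        try:
            cc[k] = lagged_correlation(seq, k, first_mask=first_mask)
        except ValueError:
            cc[k] = np.nan
    return SummaryStats(
        n_periods=len(durations),
        mu1=mom.mu1,
        mu2=mom.mu2,
        mu3=mom.mu3,
        cv=mom.cv,
        rel_skew=mom.rel_skew,
        cc=cc,
        mean_de_rev=float(np.mean(de)) if de is not None and len(de) else np.nan,
        mean_ebar_rev=float(np.mean(ebar)) if ebar is not None and len(ebar) else np.nan,
        flagged=flagged,
    )


def _condition_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def simulate_condition_periods(
    params: ModelParams,
    c: float,
    c_prime: float,
    n_periods: int,
    seed: int,
    dt: float = DEFAULT_DT,
    burn_in: float = 30.0,
    hysteresis: float = 0.2,
    max_sim_time: float | None = None,
):
    """Simulate one contrast condition until ``n_periods`` dominance periods
    are collected (after burn-in), using the compiled online extractor.

    Returns (durations, labels, e_end, e2_end, complete) where label +1
    marks dominance of the percept driven by contrast ``c`` and the
    evidence fractions are sampled at the reversal ending each period.
    """
    if max_sim_time is None:
        max_sim_time = burn_in + 60.0 * n_periods  # generous: periods are seconds
    I1 = contrast_transfer(c, params.gamma)
    I2 = contrast_transfer(c_prime, params.gamma)
    max_steps = int(max_sim_time / dt)
    start_first = bool(np.random.default_rng(seed).integers(0, 2))
    durs, labels, e_end, e2_end, n, _ = _kernels.sim_periods(
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
        burn_in,
        1.0 - hysteresis,
        hysteresis,
        n_periods,
        max_steps,
        seed % (2**32),
        start_first,
    )
    return durs, labels, e_end, e2_end, bool(n >= n_periods)


def run_contrast_grid(
    params: ModelParams,
    contrast_levels: Sequence[float] = DEFAULT_CONTRAST_LEVELS,
    target_periods: int = 1000,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    burn_in: float = 30.0,
    hysteresis: float = 0.2,
    cc_lags: Sequence[int] = (1, 2),
    max_sim_time_per_condition: float | None = None,
) -> GridResult:
    """Simulate all contrast combinations and summarize each merged cell.

    Conditions with ``c >= c'`` are simulated (mirror conditions are
    statistically identical); every dominance period is then keyed by
    ``(c_dom, c_sup)`` — the contrast feeding the dominant percept first —
    which populates the full ordered grid.  Each cell receives at least
    ``target_periods`` periods, relying on the strict alternation of
    dominance labels.  A condition that fails to produce enough reversals
    within the wall limit yields flagged cells rather than an error.
    """
    levels = tuple(sorted(contrast_levels))
    n_cond = len(levels) * (len(levels) + 1) // 2
    seeds = _condition_seeds(seed, n_cond)
    cells: dict[tuple, SummaryStats] = {}
    k = 0
    for i, c in enumerate(levels):
        for j, c2 in enumerate(levels):
            if c2 > c:
                continue
            diagonal = c == c2
            n_request = target_periods if diagonal else 2 * target_periods + 2
            durs, labels, e_end, e2_end, complete = simulate_condition_periods(
                params, c, c2, n_request, seeds[k], dt, burn_in, hysteresis,
                max_sim_time_per_condition,
            )
            k += 1
            de = np.abs(e_end - e2_end)
            ebar = 0.5 * (e_end + e2_end)
            if diagonal:
                keys = {1: (c, c2), -1: (c, c2)}
            else:
                keys = {1: (c, c2), -1: (c2, c)}
            for lab in ((1,) if diagonal else (1, -1)):
                mask = np.ones(len(durs), bool) if diagonal else labels == lab
                key = keys[lab]
                if mask.sum() < 3:
                    cells[key] = SummaryStats(
                        n_periods=int(mask.sum()), mu1=np.nan, mu2=np.nan,
                        mu3=np.nan, cv=np.nan, rel_skew=np.nan, flagged=True,
                    )
                    continue
                cells[key] = summarize_durations(
                    durs[mask],
                    cc_lags=cc_lags,
                    first_mask=None if diagonal else mask,
                    full_durations=durs,
                    de=de[mask],
                    ebar=ebar[mask],
                    flagged=not complete,
                )
    return GridResult(levels=levels, cells=cells, target_periods=target_periods,
                      seed=seed, dt=dt)


# ---------------------------------------------------------------------
# Fisher information capture


def fisher_info_ratio(
    N: int = 25,
    w: float = 2.5,
    input_mean_grid=None,
    input_sd: float = 0.8,
    n_samples: int = 20,
    n_reps: int = 6000,
    window: float = 1.0,
    seed: int = 0,
) -> float:
    """Fraction of the ideal observer's Fisher information captured by
    opponent pools of bistable variables.

    Protocol: each of ``n_samples`` input samples s ~ N(mu, input_sd) drives
    a fresh, initially inactive opponent pair of pools — one coupled +w, one
    coupled -w, mirroring how conflicting evidence excites one evidence pool
    and counts against the other — for ``window`` baseline relaxation times
    (baseline rate 1).  The readout is the summed differential count.  The
    Fisher information about mu carried by the readout is estimated as
    (d<n>/dmu)^2 / Var(n) on a grid of input means and divided by the
    information in the raw samples, n_samples / input_sd^2.

    A pool variable starting inactive under constant rates nu+- is active
    after time T with probability x_inf (1 - exp(-T/tau)); the counts are
    sampled exactly from the resulting binomial law.

    The default input SD of 0.8 keeps the per-sample log-odds swing
    w * s (~2 at w = 2.5) within the sensitive range of the activation
    sigmoid: capture degrades through saturation for much wider inputs and
    through channel noise for much narrower ones.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if input_sd <= 0:
        raise ValueError("input_sd must be > 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    if input_mean_grid is None:
        input_mean_grid = np.linspace(-0.5, 0.5, 7) * input_sd
    mu_grid = np.asarray(input_mean_grid, dtype=float)
    if len(mu_grid) < 3:
        raise ValueError("need at least 3 grid points to estimate a slope")
    means = np.empty(len(mu_grid))
    varis = np.empty(len(mu_grid))
    for i, mu in enumerate(mu_grid):
        tot = np.zeros(n_reps, dtype=np.int64)
        for _ in range(n_samples):
            s = rng.normal(mu, input_sd, n_reps)
            for sign in (1.0, -1.0):
                du = np.clip(sign * w * s, -80.0, 80.0)
                nu_p = 0.5 * np.exp(0.5 * du)
                nu_m = 0.5 * np.exp(-0.5 * du)
                x_inf = nu_p / (nu_p + nu_m)
                p = x_inf * (-np.expm1(-(nu_p + nu_m) * window))
                tot += np.int64(sign) * rng.binomial(N, p)
        means[i] = tot.mean()
        varis[i] = tot.var()
    slope = (means[2:] - means[:-2]) / (mu_grid[2:] - mu_grid[:-2])
    fi_pool = slope**2 / varis[1:-1]
    fi_ideal = n_samples / input_sd**2
    return float(np.mean(fi_pool) / fi_ideal)
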