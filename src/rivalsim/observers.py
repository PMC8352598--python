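"""Observer key-press data: parsing, preprocessing, and synthetic fixtures.

Observer reports arrive as continuous key-press records: during a 120 s
block the observer holds one of two keys while the corresponding grating is
exclusively visible and releases both during mixed percepts.  The package's
columnar dialect is a CSV with columns ``observer,block,c_left,c_right,t,
state`` where state is one of ``L``, ``R``, ``N`` sampled at the display
rate (60 Hz by default).

The synthetic-observer generator draws gamma-distributed dominance periods
with an optional AR(1) log-scale modulation producing positive serial
correlation, so that the full parsing/statistics pipeline can be exercised
against known ground truth.  The calibration utilities quantify sampling
error of the summary statistics on independent gamma samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .stats import DominanceSeries, duration_moments, lagged_correlation

__all__ = [
    "CalibrationReport",
    "parse_keypress",
    "preprocess_block",
    "normalize_observer",
    "synth_observer",
    "series_to_keypress",
    "sem_calibration",
    "merge_symmetric",
]

BLOCK_LENGTH = 120.0  # s
ANALYSIS_START = 30.0  # s; dominance periods are taken from the final 90 s
SAMPLE_RATE = 60.0  # Hz, display refresh
GRAND_MEAN = 2.5  # s, all-condition all-observer average duration
DEFAULT_GAMMA_SHAPE = 1 / 0.55**2  # midpoint of the observed cV band 0.5-0.6

_STATES = {"L", "R", "N"}


@dataclass
class CalibrationReport:
    """Sampling variability of the summary statistics on gamma samples."""

    n_samples: int
    gamma_shape: float
    n_reps: int
    rel_sem_mean: float
    rel_sem_cv: float
    rel_sem_rel_skew: float
    sd_cc1: float


def parse_keypress(
    records: pd.DataFrame,
    block_length: float = BLOCK_LENGTH,
    analysis_start: float = ANALYSIS_START,
) -> list[DominanceSeries]:
    """Extract dominance periods from key-press records, one series per block.

    Contiguous runs of a single key within the final 90 s of each block
    become dominance periods; ``N`` samples (mixed percepts) separate
    periods and contribute no duration.  Runs clipped by the analysis window
    (still held at either boundary) are discarded, as a truncated duration
    is not a dominance duration.
    """
    required = {"observer", "block", "c_left", "c_right", "t", "state"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = set(records["state"].unique()) - _STATES
    if bad:
        raise ValueError(f"unknown key states: {sorted(bad)}")
    if (records["t"].min() < 0) or (records["t"].max() > block_length):
        raise ValueError(f"times must lie within [0, {block_length}] s")
    out = []
    for (obs, blk), g in records.groupby(["observer", "block"], sort=True):
        g = g.sort_values("t")
        t = g["t"].to_numpy(dtype=float)
        state = g["state"].to_numpy()
        cond = (float(g["c_left"].iloc[0]), float(g["c_right"].iloc[0]))
        # run-length encode the state sequence
        change = np.flatnonzero(state[1:] != state[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(state)]))
        labels, onsets, durations = [], [], []
        dt = np.median(np.diff(t)) if len(t) > 1 else 0.0
        for s0, s1 in zip(starts, ends):
            key = state[s0]
            if key == "N":
                continue
            t_on = t[s0]
            t_off = t[s1 - 1] + dt  # run extends to the next sample
            if t_on < analysis_start or t_off > block_length - dt / 2 + 1e-9:
                continue  # clipped by the window
            labels.append(1 if key == "L" else -1)
            onsets.append(t_on)
            durations.append(t_off - t_on)
        if durations:
            out.append(
                DominanceSeries(
                    np.array(labels),
                    np.array(onsets),
                    np.array(durations),
                    condition=cond,
                    source="observer",
                    extras={"observer": obs, "block": blk},
                )
            )
    return out


def preprocess_block(durations) -> np.ndarray:
    """Remove the mean linear trend from a block's durations, preserving the
    block mean.

    An ordinary least-squares line is fitted over (period index, duration)
    and the slope component subtracted; slow drifts of alternation rate
    within a block would otherwise masquerade as serial correlation.
    """
    d = np.asarray(durations, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 durations to detrend")
    idx = np.arange(len(d), dtype=float)
    slope = np.polyfit(idx, d, 1)[0]
    return d - slope * (idx - idx.mean())


def normalize_observer(durations, observer_mean: float, grand_mean: float = GRAND_MEAN):
    """Rescale one observer's durations by grand_mean / observer_mean.

    After rescaling, the observer's all-condition average equals the
    all-condition all-observer average, making dominance periods comparable
    across observers.
    """
    if observer_mean <= 0 or grand_mean <= 0:
        raise ValueError("means must be > 0")
    return np.asarray(durations, dtype=float) * (grand_mean / observer_mean)


def _ar1_log_variance(rho: float, shape: float, ar_coef: float) -> float:
    """Latent log-normal variance v such that the lag-1 correlation of
    gamma durations modulated by exp(z), z ~ AR(1)(ar_coef, v), equals rho.

    cc1(v) = (exp(a v) - 1) / ((1 + 1/k) exp(v) - 1); the smaller root is
    used.  Raises if rho exceeds the attainable maximum.
    """
    if rho == 0:
        return 0.0

    def cc1(v):
        return np.expm1(ar_coef * v) / ((1 + 1 / shape) * np.exp(v) - 1)

    vs = np.linspace(1e-4, 8.0, 400)
    vals = np.array([cc1(v) for v in vs])
    peak = vals.max()
    if rho > peak:
        raise ValueError(
            f"serial_rho={rho} not attainable with gamma shape {shape} "
            f"(max {peak:.3f})"
        )
    i_peak = int(vals.argmax())
    return brentq(lambda v: cc1(v) - rho, 1e-6, vs[i_peak])


def synth_observer(
    n_periods: int,
    mean_s: float = GRAND_MEAN,
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    serial_rho: float = 0.0,
    seed: int = 0,
    ar_coef: float = 0.7,
) -> DominanceSeries:
    """Generate a synthetic observer's dominance series.

    Durations are gamma distributed with the requested mean and shape; a
    latent AR(1) process modulates the scale multiplicatively (log-normal,
    mean-one) and is calibrated so that the lag-1 serial correlation of the
    durations equals ``serial_rho``, decaying geometrically at longer lags.
    Labels alternate strictly, as in rivalry reports of clear visibility.
    """
    if gamma_shape <= 0:
        raise ValueError("gamma_shape must be > 0")
    if not -1 < serial_rho < 1:
        raise ValueError("serial_rho must be in (-1, 1)")
    if serial_rho < 0:
        raise ValueError("negative serial correlation is not supported")
    rng = np.random.default_rng(seed)
    v = _ar1_log_variance(serial_rho, gamma_shape, ar_coef)
    z = np.empty(n_periods)
    if v > 0:
        z[0] = rng.normal(0, np.sqrt(v))
        innov_sd = np.sqrt(v * (1 - ar_coef**2))
        for i in range(1, n_periods):
            z[i] = ar_coef * z[i - 1] + rng.normal(0, innov_sd)
    else:
        z[:] = 0.0
    modulation = np.exp(z - v / 2)  # mean-one log-normal
    base = rng.gamma(gamma_shape, mean_s / gamma_shape, n_periods)
    durations = base * modulation
    labels = np.empty(n_periods, dtype=int)
    labels[::2] = 1
    labels[1::2] = -1
    onsets = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
    return DominanceSeries(
        labels, onsets, durations, condition=None, source="synthetic",
        extras={"serial_rho": serial_rho, "gamma_shape": gamma_shape},
    )


def series_to_keypress(
    series: DominanceSeries,
    observer: str = "synth",
    condition: tuple = (1.0, 1.0),
    none_fraction: float = 0.25,
    block_length: float = BLOCK_LENGTH,
    sample_rate: float = SAMPLE_RATE,
    seed: int = 0,
) -> pd.DataFrame:
    """Render a dominance series as key-press records in the CSV dialect.

    Periods are laid out sequentially with exponentially distributed ``N``
    gaps (mixed percepts) sized so that roughly ``none_fraction`` of
    presentation time is unreported, split into 120 s blocks.  Periods
    straddling a block boundary are truncated by the block end, exactly as
    a real recording would truncate them.
    """
    if not 0 <= none_fraction < 1:
        raise ValueError("none_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    gap_mean = series.durations.mean() * none_fraction / (1 - none_fraction)
    n_samp = int(round(block_length * sample_rate))
    rows = []
    block = 0
    t_in_block = 0.0
    states = np.full(n_samp, "N", dtype="<U1")

    def flush():
        nonlocal states, block
        ts = np.arange(n_samp) / sample_rate
        rows.append(
            pd.DataFrame(
                {
                    "observer": observer,
                    "block": block,
                    "c_left": condition[0],
                    "c_right": condition[1],
                    "t": ts,
                    "state": states,
                }
            )
        )
        states = np.full(n_samp, "N", dtype="<U1")
        block += 1

    for lab, dur in zip(series.labels, series.durations):
        if gap_mean > 0:
            t_in_block += rng.exponential(gap_mean)
        while t_in_block >= block_length:
            flush()
            t_in_block -= block_length
        remaining = dur
        while remaining > 0:
            i0 = int(t_in_block * sample_rate)
            seg = min(remaining, block_length - t_in_block)
            i1 = min(int((t_in_block + seg) * sample_rate), n_samp)
            states[i0:i1] = "L" if lab == 1 else "R"
            t_in_block += seg
            remaining -= seg
            if t_in_block >= block_length:
                flush()
                t_in_block = 0.0
                break  # the truncated tail is dropped, as in a real block
    if np.any(states != "N"):
        flush()
    return pd.concat(rows, ignore_index=True)


def sem_calibration(
    n_samples: int = 1000,
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    n_reps: int = 2000,
    seed: int = 0,
) -> CalibrationReport:
    """Sampling variability of the summary statistics on iid gamma draws.

    Draws ``n_reps`` independent sets of ``n_samples`` gamma durations,
    computes mean, cV, relative skewness and cc1 per set, and reports the
    across-set SD — relative to the statistic's mean for the moments,
    absolute for cc1.
    """
    rng = np.random.default_rng(seed)
    x = rng.gamma(gamma_shape, 1.0, size=(n_reps, n_samples))
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    mu3 = ((x - mean[:, None]) ** 3).mean(axis=1)
    cv = np.sqrt(var) / mean
    rel_skew = mu3 * mean / var**2
    xc = x - mean[:, None]
    num = (xc[:, :-1] * xc[:, 1:]).mean(axis=1)
    cc1 = num / (x[:, :-1].std(axis=1) * x[:, 1:].std(axis=1))
    return CalibrationReport(
        n_samples=n_samples,
        gamma_shape=gamma_shape,
        n_reps=n_reps,
        rel_sem_mean=float(mean.std() / mean.mean()),
        rel_sem_cv=float(cv.std() / cv.mean()),
        rel_sem_rel_skew=float(rel_skew.std() / rel_skew.mean()),
        sd_cc1=float(cc1.std()),
    )


def merge_symmetric(series_list: list[DominanceSeries]) -> dict:
    """Pool dominance periods from mirror conditions into (c_dom, c_sup) cells.

    Each period is keyed by the contrast seen by the dominant eye and the
    contrast seen by the suppressed eye, so a (1, 1/2) left-dominant period
    and a (1/2, 1) right-dominant period land in the same cell.  Returns a
    dict mapping (c_dom, c_sup) to an array of durations.
    """
    out: dict[tuple, list] = {}
    for s in series_list:
        if s.condition is None:
            raise ValueError("series lacks a (c_left, c_right) condition label")
        c_left, c_right = s.condition
        for lab, dur in zip(s.labels, s.durations):
            if lab == 1:
                key = (c_left, c_right)
            elif lab == -1:
                key = (c_right, c_left)
            else:
                raise ValueError(f"unknown dominance label {lab!r}")
            out.setdefault(key, []).append(dur)
    return {k: np.asarray(v) for k, v in out.items()}
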