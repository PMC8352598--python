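"""Fitting objective, random-restart search, sensitivity parabolas, and
solution-ensemble PCA for the hierarchical model.

The objective compares four observables between model and target: the grid
of mean dominance durations <T>, the grid of coefficients of variation cV,
and two scalars — relative skewness gamma1/cV and lag-1 correlation cc1
(grid averages).  The fit error is the weighted mean of per-observable
relative errors with weights (1, 1, 1, 1/4), de-emphasizing the noisy
correlation coefficient.

Model evaluations are stochastic; all searches therefore use common random
numbers (a fixed simulation seed per evaluation) so that comparisons
between parameter vectors are noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams
from .stats import GridResult, run_contrast_grid

__all__ = [
    "FitTargets",
    "FitResult",
    "fit_error",
    "grid_observables",
    "targets_from_grid",
    "evaluate_fit",
    "random_restart_search",
    "profile_objective",
    "sensitivity_scan",
    "solution_manifold_pca",
    "DEFAULT_BOUNDS",
]

FIT_WEIGHTS = (1.0, 1.0, 1.0, 0.25)

# search ranges: generous brackets around the fitted operating point
DEFAULT_BOUNDS = {
    "inv_nu_e": (0.5, 8.0),
    "inv_nu_r": (0.005, 0.1),
    "ue0": (-4.0, 0.0),
    "ur0": (-10.0, -1.0),
    "w_vis": (0.5, 5.0),
    "w_exc": (50.0, 300.0),
    "w_inh": (5.0, 100.0),
    "w_comp": (10.0, 100.0),
    "w_coop": (5.0, 50.0),
    "w_supp": (0.5, 8.0),
    "gamma": (0.01, 0.5),
}


@dataclass
class FitTargets:
    """Target observables: matrices over (c_dom, c_sup) plus two scalars."""

    levels: tuple
    mean_t: np.ndarray
    cv: np.ndarray
    rel_skew: float
    cc1: float


@dataclass
class FitResult:
    params: ModelParams
    efit: float
    deltas: dict
    trace: list = field(default_factory=list)
    seed: int = 0


def grid_observables(grid: GridResult):
    """Observables of a grid run: (<T> matrix, cV matrix, scalar rel_skew,
    scalar cc1), the scalars averaged over all cells."""
    mean_t = grid.cell_matrix("mu1")
    cv = grid.cell_matrix("cv")
    rel_skew = float(np.nanmean(grid.cell_matrix("rel_skew")))
    cc1 = float(np.nanmean(grid.cell_matrix("cc1")))
    return mean_t, cv, rel_skew, cc1


def targets_from_grid(grid: GridResult) -> FitTargets:
    mean_t, cv, rel_skew, cc1 = grid_observables(grid)
    return FitTargets(levels=grid.levels, mean_t=mean_t, cv=cv,
                      rel_skew=rel_skew, cc1=cc1)


def fit_error(model_stats, target_stats: FitTargets, weights=FIT_WEIGHTS):
    """Weighted mean of per-observable relative errors.

    Per observable, delta = mean(|X_mod - X_exp|) / mean(X_exp) over cells
    (plain relative error for the scalars); Efit = sum(w_i delta_i) /
    sum(w_i).  NaN cells (flagged, unconverged) are excluded pairwise; a
    shape mismatch between model and target grids is an error.
    """
    if isinstance(model_stats, GridResult):
        mean_t, cv, rel_skew, cc1 = grid_observables(model_stats)
    else:
        mean_t, cv, rel_skew, cc1 = model_stats
    mean_t = np.asarray(mean_t, float)
    cv = np.asarray(cv, float)
    if mean_t.shape != np.shape(target_stats.mean_t) or cv.shape != np.shape(target_stats.cv):
        raise ValueError("model and target grids have mismatched shapes")
    deltas = {}
    for name, mod, exp in (
        ("mean_t", mean_t, np.asarray(target_stats.mean_t, float)),
        ("cv", cv, np.asarray(target_stats.cv, float)),
    ):
        ok = np.isfinite(mod) & np.isfinite(exp)
        if not ok.any():
            deltas[name] = np.inf
        else:
            deltas[name] = float(np.abs(mod[ok] - exp[ok]).mean() / exp[ok].mean())
    for name, mod, exp in (("rel_skew", rel_skew, target_stats.rel_skew),
                           ("cc1", cc1, target_stats.cc1)):
        deltas[name] = float(abs(mod - exp) / abs(exp)) if exp != 0 else np.inf
    w = np.asarray(weights, float)
    vals = np.array([deltas[k] for k in ("mean_t", "cv", "rel_skew", "cc1")])
    efit = float((w * vals).sum() / w.sum())
    return efit, deltas


def evaluate_fit(
    params: ModelParams,
    target_stats: FitTargets,
    periods_per_eval: int = 300,
    eval_seed: int = 12345,
    weights=FIT_WEIGHTS,
    dt: float = 5e-4,
):
    """Efit of one parameter vector under common random numbers.

    Two calls with identical parameters and ``eval_seed`` return identical
    values, enabling noise-free comparisons inside searches.
    """
    grid = run_contrast_grid(
        params,
        contrast_levels=target_stats.levels,
        target_periods=periods_per_eval,
        seed=eval_seed,
        dt=dt,
    )
    return fit_error(grid, target_stats, weights=weights)


def _to_vector(params: ModelParams, names) -> np.ndarray:
    return np.array([getattr(params, n) for n in names], float)


def _from_vector(base: ModelParams, names, x) -> ModelParams:
    return base.replace(**{n: float(v) for n, v in zip(names, x)})


def random_restart_search(
    target_stats: FitTargets,
    bounds: dict | None = None,
    n_runs: int = 4,
    n_iters: int = 25,
    periods_per_eval: int = 300,
    seed: int = 0,
    base_params: ModelParams | None = None,
    start_at_base: bool = False,
    step0: float = 0.25,
    dt: float = 5e-4,
) -> list[FitResult]:
    """Random-restart stochastic descent over the model parameters.

    Each run starts from a random point in ``bounds`` (log-uniform for
    positive quantities, uniform otherwise) and performs simultaneous-
    perturbation (SPSA) descent in the scaled parameter space with a
    geometrically decaying step, evaluating Efit with common random numbers.
    Returns all terminal points sorted by Efit; non-improving runs are
    reported as found.
    """
    bounds = bounds or DEFAULT_BOUNDS
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    base = base_params or ModelParams()
    rng = np.random.default_rng(seed)
    results = []
    for run in range(n_runs):
        if start_at_base and run == 0:
            x = _to_vector(base, names)
        else:
            u = rng.uniform(size=len(names))
            positive = lo > 0
            x = np.where(
                positive,
                np.exp(np.log(np.clip(lo, 1e-12, None)) + u * (np.log(np.clip(hi, 1e-12, None)) - np.log(np.clip(lo, 1e-12, None)))),
                lo + u * (hi - lo),
            )
        eval_seed = int(rng.integers(2**31))
        scale = hi - lo
        trace = []
        best_x, best_e = x.copy(), np.inf

        def f(vec):
            p = _from_vector(base, names, np.clip(vec, lo, hi))
            e, _ = evaluate_fit(p, target_stats, periods_per_eval, eval_seed, dt=dt)
            return e

        e0 = f(x)
        trace.append((x.copy(), e0))
        if e0 < best_e:
            best_x, best_e = x.copy(), e0
        for t in range(n_iters):
            c_t = step0 * 0.5 * (0.85**t)
            a_t = step0 * (0.85**t)
            delta = rng.choice([-1.0, 1.0], size=len(names))
            e_plus = f(x + c_t * scale * delta)
            e_minus = f(x - c_t * scale * delta)
            ghat = (e_plus - e_minus) / (2 * c_t) * delta
            x = np.clip(x - a_t * scale * ghat / max(np.abs(ghat).max(), 1e-12), lo, hi)
            e_x = f(x)
            trace.append((x.copy(), e_x))
            if e_x < best_e:
                best_x, best_e = x.copy(), e_x
        p_best = _from_vector(base, names, best_x)
        _, deltas = evaluate_fit(p_best, target_stats, periods_per_eval, eval_seed, dt=dt)
        results.append(FitResult(params=p_best, efit=best_e, deltas=deltas,
                                 trace=trace, seed=eval_seed))
    return sorted(results, key=lambda r: r.efit)


def profile_objective(
    target_stats: FitTargets,
    param_name: str,
    values,
    base_params: ModelParams | None = None,
    periods_per_eval: int = 300,
    eval_seed: int = 12345,
    dt: float = 5e-4,
):
    """Efit along a 1-D slice of parameter space (common random numbers)."""
    base = base_params or ModelParams()
    out = np.empty(len(values))
    for i, v in enumerate(values):
        p = base.replace(**{param_name: float(v)})
        out[i], _ = evaluate_fit(p, target_stats, periods_per_eval, eval_seed, dt=dt)
    return np.asarray(values, float), out


def sensitivity_scan(
    params_opt: ModelParams,
    target_stats: FitTargets,
    param_name: str,
    n_points: int = 30,
    span: float = 0.15,
    periods_per_eval: int = 300,
    eval_seed: int = 12345,
    dt: float = 5e-4,
):
    """Quadratic sensitivity profile of Efit around an optimum.

    Evaluates Efit at ``n_points`` values within ``+-span`` (relative) of
    the optimal parameter, fits a parabola, and reports the curvature with
    a 95% confidence interval and the vertex location.  A convex profile
    with a vertex near the optimum confirms local optimality.
    """
    v0 = getattr(params_opt, param_name)
    values = v0 * (1 + np.linspace(-span, span, n_points))
    xs, es = profile_objective(target_stats, param_name, values, params_opt,
                               periods_per_eval, eval_seed, dt=dt)
    # quadratic fit with parameter covariance from residual variance
    X = np.vander(xs - v0, 3)  # columns (x^2, x, 1)
    coef, res, *_ = np.linalg.lstsq(X, es, rcond=None)
    dof = max(len(xs) - 3, 1)
    s2 = float(res[0]) / dof if len(res) else float(((X @ coef - es) ** 2).sum()) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    curv_se = float(np.sqrt(cov[0, 0]))
    a, b, c = coef
    vertex = v0 - b / (2 * a) if a != 0 else np.nan
    warn = not np.isfinite(vertex) or abs(a) < 2 * curv_se
    return {
        "param": param_name,
        "values": xs,
        "efit": es,
        "curvature": float(a),
        "curvature_ci95": (float(a - 1.96 * curv_se), float(a + 1.96 * curv_se)),
        "convex": bool(a > 0),
        "vertex": float(vertex),
        "optimum": float(v0),
        "degenerate": bool(warn),
    }


def solution_manifold_pca(fit_results, efit_cutoff: float | None = None,
                          var_target: float = 0.95):
    """PCA of the ensemble of (sub)optimal parameter vectors.

    Parameter vectors are standardized per coordinate and decomposed by
    SVD; returns the explained-variance ratios and the number of components
    needed to reach ``var_target``.  A low count relative to the parameter
    dimension indicates redundancy — few effective degrees of freedom.
    """
    if efit_cutoff is not None:
        fit_results = [r for r in fit_results if r.efit <= efit_cutoff]
    if len(fit_results) < 3:
        raise ValueError("need at least 3 solutions below the cutoff")
    if isinstance(fit_results[0], FitResult):
        names = [n for n in DEFAULT_BOUNDS]
        M = np.array([[getattr(r.params, n) for n in names] for r in fit_results])
    else:
        M = np.asarray(fit_results, float)
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    M = M / sd
    s = np.linalg.svd(M, compute_uv=False)
    var = s**2
    ratios = var / var.sum()
    cum = np.cumsum(ratios)
    n_components = int(np.searchsorted(cum, var_target) + 1)
    return {"explained_variance_ratio": ratios, "n_components": n_components,
            "n_solutions": len(fit_results)}
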