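"""File formats: trajectory CSV + JSON sidecar, grid dumps, configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SystemTrajectory
from .params import AltParams, ModelParams
from .stats import GridResult, SummaryStats

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_grid",
    "read_targets",
    "write_targets",
    "load_config",
]


def write_trajectory(traj: SystemTrajectory, path) -> list[Path]:
    """Write a trajectory as CSV (time,e,e_prime,r,r_prime) plus a JSON
    sidecar holding parameters, contrasts and seed."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": traj.times,
            "e": traj.e,
            "e_prime": traj.e_prime,
            "r": traj.r,
            "r_prime": traj.r_prime,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "c": traj.c,
        "c_prime": traj.c_prime,
        "dt": traj.dt,
        "seed": traj.seed,
        "params": traj.params.to_dict() if traj.params else None,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return [path, sidecar]


def read_trajectory(path) -> SystemTrajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SystemTrajectory(
        df["time"].to_numpy(),
        df["e"].to_numpy(),
        df["e_prime"].to_numpy(),
        df["r"].to_numpy(),
        df["r_prime"].to_numpy(),
        meta["c"],
        meta["c_prime"],
        meta["dt"],
        seed=meta.get("seed"),
        params=ModelParams.from_dict(meta["params"]) if meta.get("params") else None,
    )


def write_grid(grid: GridResult, base_path) -> list[Path]:
    """Tidy CSV (one row per merged cell) plus a JSON full dump."""
    base = Path(base_path)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    grid.to_frame().to_csv(csv_path, index=False, float_format="%.6g")
    dump = {
        "levels": list(grid.levels),
        "target_periods": grid.target_periods,
        "seed": grid.seed,
        "dt": grid.dt,
        "cells": {
            f"{cd:g},{cs:g}": _cell_dict(s) for (cd, cs), s in sorted(grid.cells.items())
        },
    }
    json_path.write_text(json.dumps(dump, indent=2))
    return [csv_path, json_path]


def _cell_dict(s: SummaryStats) -> dict:
    d = dataclasses.asdict(s)
    d["cc"] = {str(k): _jsonable(v) for k, v in s.cc.items()}
    d["bi"] = {str(k): _jsonable(v) for k, v in s.bi.items()}
    return {k: _jsonable(v) for k, v in d.items()}


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


def write_targets(targets, path) -> Path:
    """Fit-targets JSON: mean_t and cv matrices, rel_skew and cc1 scalars."""
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "levels": list(targets.levels),
                "mean_t": np.asarray(targets.mean_t).tolist(),
                "cv": np.asarray(targets.cv).tolist(),
                "rel_skew": targets.rel_skew,
                "cc1": targets.cc1,
            },
            indent=2,
        )
    )
    return path


def read_targets(path):
    from .fitting import FitTargets

    d = json.loads(Path(path).read_text())
    return FitTargets(
        levels=tuple(d["levels"]),
        mean_t=np.asarray(d["mean_t"], float),
        cv=np.asarray(d["cv"], float),
        rel_skew=float(d["rel_skew"]),
        cc1=float(d["cc1"]),
    )


def load_config(path) -> dict:
    """Load a YAML (or JSON) config with sections model/simulation/
    statistics/fit/alt; missing sections default to empty dicts."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for section in ("model", "simulation", "statistics", "fit", "alt"):
        cfg.setdefault(section, {})
    return cfg


def params_from_config(cfg: dict) -> ModelParams:
    return ModelParams.from_dict(cfg.get("model", {}))


def alt_params_from_config(cfg: dict) -> AltParams:
    return AltParams.from_dict(cfg.get("alt", {}))
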