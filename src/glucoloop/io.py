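"""File I/O: trajectory CSV, parameter configs, structured results.

Conventions are fixed, with no unit inference: time in hours under the
header ``time_h``, glucose in mmol/L under ``glucose_mmol_L`` (optional
``insulin_mU_L``, ``glucagon_au``).  CSV is comma-separated, '.' decimal,
UTF-8, header mandatory.  Structured results go to JSON with a parameter
echo and the seed, so that a run can be reproduced from its output alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .fitting import PeakScanResult
from .model import Trajectory
from .params import LumpedParams, MealSpec

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "write_results",
    "load_config",
    "TrajectoryParseError",
]

_REQUIRED = ("time_h", "glucose_mmol_L")
_OPTIONAL = ("insulin_mU_L", "glucagon_au")
_FLOAT_FMT = "%.12g"


class TrajectoryParseError(ValueError):
    """A trajectory file violates the CSV contract; the message names the row."""


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read and validate a trajectory CSV.

    Requires the mandatory header columns, strictly increasing time and
    finite positive glucose; extra columns are ignored.  Errors name the
    offending column or data row (1-based, excluding the header).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise TrajectoryParseError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(frame.columns)}")
    cols = {}
    for col in _REQUIRED + tuple(c for c in _OPTIONAL if c in frame.columns):
        values = pd.to_numeric(frame[col], errors="coerce").to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise TrajectoryParseError(
                f"{path}: non-numeric or non-finite value in column "
                f"{col!r} at data row {bad[0] + 1}")
        cols[col] = values
    t = cols["time_h"]
    non_increasing = np.flatnonzero(np.diff(t) <= 0)
    if non_increasing.size:
        row = non_increasing[0] + 2
        raise TrajectoryParseError(
            f"{path}: time_h not strictly increasing at data row {row} "
            f"(t={t[row - 1]!r} after t={t[row - 2]!r})")
    g = cols["glucose_mmol_L"]
    nonpos = np.flatnonzero(g <= 0)
    if nonpos.size:
        raise TrajectoryParseError(
            f"{path}: non-positive glucose at data row {nonpos[0] + 1}")
    i_pk = int(np.argmax(g))
    return Trajectory(
        times=t, glucose=g,
        insulin=cols.get("insulin_mU_L"), glucagon=cols.get("glucagon_au"),
        baseline=float(g[0]), peak_value=float(g[i_pk]),
        peak_time=float(t[i_pk]))


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory CSV that round-trips through :func:`read_trajectory`."""
    data = {"time_h": traj.times, "glucose_mmol_L": traj.glucose}
    if traj.insulin is not None:
        data["insulin_mU_L"] = traj.insulin
    if traj.glucagon is not None:
        data["glucagon_au"] = traj.glucagon
    pd.DataFrame(data).to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(
    result: Any,
    path: Union[str, Path],
    fmt: Optional[str] = None,
    seed: Optional[int] = None,
    params_echo: Optional[dict] = None,
) -> None:
    """Write a result object to CSV (tabular) or JSON (structured).

    Trajectories and peak scans default to CSV; everything else to JSON.
    JSON payloads carry the seed and a parameter echo when provided, and the
    bytes are identical across runs with identical inputs and seed.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "json"
    if fmt == "csv":
        if isinstance(result, Trajectory):
            write_trajectory(result, path)
            return
        if isinstance(result, PeakScanResult):
            pd.DataFrame({"w_mmol": result.w_grid,
                          "peak_mmol_L": result.peaks}).to_csv(
                path, index=False, float_format=_FLOAT_FMT)
            return
        raise ValueError(f"no CSV layout for {type(result).__name__}")
    if fmt != "json":
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'json')")
    payload = {"result": _to_jsonable(result)}
    if seed is not None:
        payload["seed"] = int(seed)
    if params_echo is not None:
        payload["params"] = _to_jsonable(params_echo)
    try:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"could not write results to {path}: {exc}") from exc


def load_config(path: Union[str, Path]) -> dict:
    """Load a flat key-value parameter config from JSON or YAML.

    Recognized keys are the parameter names used throughout the package
    (lambda_y, beta, x0, delta, p, q, omega, sigma, n, kappa, w, a, k, ...);
    values must be numbers.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    bad = {k: v for k, v in raw.items() if not isinstance(v, (int, float))}
    if bad:
        raise ValueError(f"{path}: non-numeric config values: {bad}")
    return {str(k): float(v) for k, v in raw.items()}


def lumped_from_config(config: dict) -> LumpedParams:
    """Build LumpedParams from a flat config, using defaults for absent keys."""
    fields = {f.name for f in dataclasses.fields(LumpedParams)}
    return LumpedParams(**{k: v for k, v in config.items() if k in fields})


def meal_from_config(config: dict) -> MealSpec:
    """Build a MealSpec from a flat config, using defaults for absent keys."""
    fields = {f.name for f in dataclasses.fields(MealSpec)}
    return MealSpec(**{k: v for k, v in config.items() if k in fields})
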