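"""Cluster-table and configuration I/O with validation.

Cluster CSVs carry exactly the columns
``cluster_id, lon, lat, time, n_households, n_people, n_under5, p_under5,
urban, zone_id``.  ``p_under5`` is the continuous modelled response; the
read-time consistency check against the integer counts allows for the
rounding used when counts are back-filled (|p - n_under5/n_people| <=
0.5/n_people).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stgp import STGPModel

CLUSTER_COLUMNS = ["cluster_id", "lon", "lat", "time", "n_households",
                   "n_people", "n_under5", "p_under5", "urban", "zone_id"]


def read_clusters(path: str | Path) -> pd.DataFrame:
    """Read and validate a cluster CSV; violations are reported by row number."""
    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cluster file {path} is missing columns: {missing}")
    df = df[CLUSTER_COLUMNS].copy()
    df["urban"] = df["urban"].astype(bool)
    problems = []
    p = df["p_under5"].to_numpy(dtype=float)
    bad_p = np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))
    problems += [f"row {i + 2}: p_under5 = {p[i]} outside [0, 1]" for i in bad_p]
    n_people = df["n_people"].to_numpy(dtype=float)
    n_u5 = df["n_under5"].to_numpy(dtype=float)
    bad_counts = np.flatnonzero(n_u5 > n_people)
    problems += [f"row {i + 2}: n_under5 > n_people" for i in bad_counts]
    with np.errstate(divide="ignore", invalid="ignore"):
        tol = 0.5 / np.maximum(n_people, 1) + 1e-9
        incons = np.flatnonzero(np.abs(p - n_u5 / np.maximum(n_people, 1)) > tol)
    problems += [f"row {i + 2}: p_under5 inconsistent with n_under5/n_people"
                 for i in incons]
    if problems:
        raise ValueError("invalid cluster records:\n  " + "\n  ".join(problems))
    return df


def write_clusters(df: pd.DataFrame, path: str | Path) -> None:
    df[CLUSTER_COLUMNS].to_csv(path, index=False)


def write_model_json(model: STGPModel, path: str | Path, extra: dict | None = None) -> None:
    payload = model.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model(path: str | Path) -> STGPModel:
    """Model parameters from JSON or YAML."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return STGPModel.from_dict(d)


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_json(obj, path: str | Path) -> None:
    """JSON with full float round-trip precision (repr shortest form)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
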