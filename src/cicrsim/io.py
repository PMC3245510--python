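"""Result and configuration I/O: CSV time-series with a JSON manifest, and
YAML run configurations."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell import SimulationResult
from .protocols import ClampProtocol, PharmacologyConfig


def write_result(result: SimulationResult, path: str | Path) -> Path:
    """Write the time series as CSV plus a ``<path>.manifest.json`` carrying
    the column list and the fully resolved run configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.data.to_csv(path, index=False)
    manifest = dict(result.meta)
    manifest["n_rows"] = int(len(result.data))
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonable)
    return path


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def read_result(path: str | Path) -> SimulationResult:
    path = Path(path)
    df = pd.read_csv(path)
    mpath = path.with_suffix(path.suffix + ".manifest.json")
    meta = {}
    if mpath.exists():
        with open(mpath) as fh:
            meta = json.load(fh)
        cols = meta.get("columns")
        if cols and list(df.columns) != list(cols):
            raise ValueError("result file does not match its manifest")
        n = meta.get("n_rows")
        if n is not None and len(df) != n:
            raise ValueError("truncated result file")
    return SimulationResult(df, meta)


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run configuration into protocol / pharmacology /
    solver-option objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {"overrides": raw.get("parameters", {}) or {},
           "solver": raw.get("solver", {}) or {}}
    if "protocol" in raw and isinstance(raw["protocol"], dict):
        out["protocol"] = ClampProtocol(**raw["protocol"])
    elif "protocol" in raw:
        out["protocol_name"] = raw["protocol"]
    ph = raw.get("pharmacology", {}) or {}
    if "caffeine_window" in ph:
        ph["caffeine_window"] = tuple(ph["caffeine_window"])
    if "cao_schedule" in ph:
        ph["cao_schedule"] = tuple(tuple(s) for s in ph["cao_schedule"])
    out["pharmacology"] = PharmacologyConfig(**ph)
    return out
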