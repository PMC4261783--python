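"""Delimited-text time series and JSON report input/output."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .ode_models import TimeSeries, ValidationError

__all__ = ["read_timeseries", "write_timeseries", "read_report", "write_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def write_timeseries(series: TimeSeries, path: str | Path) -> None:
    """CSV layout: first column ``time``, one column per component.

    Values are written at 17 significant digits (full float64 round-trip
    precision) so a write/read cycle is lossless.
    """
    df = pd.DataFrame({"time": series.times})
    for name, row in zip(series.component_names, series.values):
        df[name] = row
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read and validate a time-series CSV written by :func:`write_timeseries`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValidationError(f"malformed time-series file {path}: {err}") from err
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise ValidationError(
            f"{path}: expected a 'time' first column plus at least one component column"
        )
    if df.isna().any().any():
        bad = int(np.argwhere(df.isna().any(axis=1).to_numpy())[0, 0]) + 2
        raise ValidationError(f"{path}: missing value near line {bad}")
    times = df["time"].to_numpy(dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValidationError(f"{path}: time column must be strictly increasing")
    names = tuple(df.columns[1:])
    values = df[list(names)].to_numpy(dtype=float).T
    return TimeSeries(times, values, names)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Write a JSON report with the schema version stamped in."""
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_jsonify(report))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
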