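"""Delimited-text and JSON round-trips for measurement records.

The CSV layout is two columns (``time, signal``) preceded by ``#``
comment lines carrying the acquisition metadata, e.g.::

    # theta = 7.0
    # TR = 2.0
    # mode = buildup
    # scale = polarization
    # noise_sigma = 0.00032
    # seed = 17
    # time_unit = s
    time,signal
    2.0,0.0117
    ...

Metadata passed as overrides to :func:`read_timeseries` wins over the
file header (the override is recorded in the returned series).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pulse_sim import TimeSeries

__all__ = ["write_timeseries", "read_timeseries", "timeseries_to_json", "timeseries_from_json"]

_META_FIELDS = ("theta", "TR", "mode", "scale", "noise_sigma", "seed", "time_unit")
_FLOAT_FIELDS = {"theta", "TR", "noise_sigma"}
_INT_FIELDS = {"seed"}


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write a series as commented CSV (columns time, signal)."""
    path = Path(path)
    with path.open("w") as fh:
        for key in _META_FIELDS:
            value = getattr(ts, key)
            if value is not None:
                fh.write(f"# {key} = {value}\n")
        pd.DataFrame({"time": ts.times, "signal": ts.signals}).to_csv(fh, index=False)


def _parse_meta_line(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if "=" not in body:
        return
    key, _, raw = body.partition("=")
    key, raw = key.strip(), raw.strip()
    if key not in _META_FIELDS:
        return
    if key in _FLOAT_FIELDS:
        meta[key] = float(raw)
    elif key in _INT_FIELDS:
        meta[key] = int(raw)
    else:
        meta[key] = raw


def read_timeseries(path, **overrides) -> TimeSeries:
    """Read a commented-CSV series; keyword overrides beat the header.

    Raises on missing columns or a non-increasing time axis.  Uniform
    spacing is checked to 1e-6 of the spacing; a non-uniform series is
    accepted but flagged in ``warnings`` (the per-point correction will
    reject it downstream).
    """
    path = Path(path)
    meta: dict = {}
    data_lines = []
    with path.open() as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                _parse_meta_line(line, meta)
            elif line.strip():
                data_lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(data_lines)))
    if not {"time", "signal"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'time' and 'signal', got {list(df.columns)}")
    times = df["time"].to_numpy(dtype=float)
    if times.size and np.any(np.diff(times) <= 0.0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    unknown = set(overrides) - set(_META_FIELDS)
    if unknown:
        raise ValueError(f"unknown metadata overrides: {sorted(unknown)}")
    meta.update({k: v for k, v in overrides.items() if v is not None})
    warnings: tuple[str, ...] = ()
    if times.size >= 3:
        dt = np.diff(times)
        if np.any(np.abs(dt - dt[0]) > 1e-6 * dt[0]):
            warnings = ("non-uniform sample spacing",)
    return TimeSeries(
        times=times,
        signals=df["signal"].to_numpy(dtype=float),
        scale=meta.get("scale", "polarization"),
        noise_sigma=meta.get("noise_sigma", 0.0),
        seed=meta.get("seed"),
        theta=meta.get("theta"),
        TR=meta.get("TR"),
        mode=meta.get("mode"),
        time_unit=meta.get("time_unit", "a.u."),
        warnings=warnings,
    )


def timeseries_to_json(ts: TimeSeries) -> str:
    """Full-metadata JSON serialization of a series."""
    payload = {key: getattr(ts, key) for key in _META_FIELDS}
    payload["times"] = ts.times.tolist()
    payload["signals"] = ts.signals.tolist()
    return json.dumps(payload)


def timeseries_from_json(text: str) -> TimeSeries:
    payload = json.loads(text)
    return TimeSeries(
        times=np.asarray(payload["times"], dtype=float),
        signals=np.asarray(payload["signals"], dtype=float),
        scale=payload.get("scale") or "polarization",
        noise_sigma=payload.get("noise_sigma") or 0.0,
        seed=payload.get("seed"),
        theta=payload.get("theta"),
        TR=payload.get("TR"),
        mode=payload.get("mode"),
        time_unit=payload.get("time_unit") or "a.u.",
    )
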