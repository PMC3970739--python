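"""File formats: signal CSV with events sidecar, per-breath TSV, results JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SignalRecord

__all__ = ["read_signal", "write_signal", "write_breaths", "read_breaths",
           "write_json", "to_jsonable"]

SIGNAL_COLUMNS = ("t", "flow", "pressure", "volume")


def _events_path(path: Path) -> Path:
    return path.with_suffix(".events.json")


def write_signal(sig: SignalRecord, path, events_path=None) -> Path:
    """Write a SignalRecord as columnar CSV (t, flow, pressure, volume) with
    the event marks in a JSON sidecar.  Numbers are printed with 10
    significant digits, which round-trips stably through read_signal.
    """
    path = Path(path)
    df = pd.DataFrame({c: getattr(sig, c) for c in SIGNAL_COLUMNS})
    df.to_csv(path, index=False, float_format="%.10g")
    ep = Path(events_path) if events_path else _events_path(path)
    with open(ep, "w") as fh:
        json.dump([[lbl, tm] for lbl, tm in sig.events], fh)
    return path


def read_signal(path, events_path=None) -> SignalRecord:
    """Read a signal CSV (header t,flow,pressure,volume) and optional events
    sidecar; validates uniform sampling to 1 ppm.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"signal file {path} is missing column {col!r}")
    t = df["t"].to_numpy(float)
    if t.size < 2:
        raise ValueError("signal must contain at least two samples")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise ValueError("time column is not increasing")
    bad = np.flatnonzero(np.abs(dt - dt0) > 1e-6 * dt0)
    if bad.size:
        raise ValueError(f"non-uniform sampling grid at index {int(bad[0])}")
    ep = Path(events_path) if events_path else _events_path(path)
    events = []
    if ep.exists():
        with open(ep) as fh:
            events = [(str(l), float(tm)) for l, tm in json.load(fh)]
    return SignalRecord(t=t, flow=df["flow"].to_numpy(float),
                        pressure=df["pressure"].to_numpy(float),
                        volume=df["volume"].to_numpy(float),
                        fs=1.0 / dt0, events=events)


def write_breaths(breaths: pd.DataFrame, path) -> Path:
    path = Path(path)
    breaths.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def read_breaths(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def to_jsonable(obj):
    """Recursively convert numpy scalars/arrays and dataclass-likes for JSON."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if hasattr(obj, "__dataclass_fields__"):
        return to_jsonable(vars(obj))
    return obj


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(to_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
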