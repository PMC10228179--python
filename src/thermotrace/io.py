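"""Trace CSV I/O.

Dialect: header row with columns ``time_s, intensity, trace_id, role`` (any
column order; extra columns ignored), UTF-8.  Laser on/off markers and
per-trace metadata travel in a JSON sidecar ``<file>.meta.json`` written by
:func:`write_traces`; when reading a bare CSV the markers must be supplied
as arguments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import MSTTrace

__all__ = ["read_traces", "write_traces", "TraceFileError"]

REQUIRED_COLUMNS = ("time_s", "intensity", "trace_id", "role")


class TraceFileError(ValueError):
    """Malformed trace file; message carries offending line numbers."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_traces(traces: list[MSTTrace], path: str | Path) -> None:
    """Write traces to one CSV plus a JSON sidecar with laser markers."""
    path = Path(path)
    frames = [pd.DataFrame({"time_s": tr.times, "intensity": tr.intensities,
                            "trace_id": tr.trace_id, "role": tr.role})
              for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")
    meta = {tr.trace_id: {"laser_on_s": tr.laser_on,
                          "laser_off_s": tr.laser_off,
                          "metadata": _jsonable(tr.metadata)}
            for tr in traces}
    _sidecar_path(path).write_text(json.dumps({"traces": meta}, indent=1))


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if v is None or isinstance(v, (bool, int, float, str)):
            out[k] = v
    return out


def read_traces(path: str | Path, laser_on: float | None = None,
                laser_off: float | None = None) -> list[MSTTrace]:
    """Read traces from CSV; markers from the sidecar or the arguments.

    Rows with unparseable time/intensity are reported with their 1-based
    file line numbers; a missing required column is a refusal naming it.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFileError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"expected {', '.join(REQUIRED_COLUMNS)}")
    for col in ("time_s", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] + 2  # header + 1-based
        if len(bad):
            raise TraceFileError(
                f"{path}: non-numeric {col} on line(s) "
                f"{', '.join(map(str, bad[:10]))}")
        if df[col].isna().any():
            bad = df.index[df[col].isna()] + 2
            raise TraceFileError(
                f"{path}: empty {col} on line(s) "
                f"{', '.join(map(str, bad[:10]))}")
        df[col] = vals
    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text()).get("traces", {})
    traces = []
    for tid, group in df.groupby("trace_id", sort=False):
        info = meta.get(str(tid), {})
        on = info.get("laser_on_s", laser_on)
        off = info.get("laser_off_s", laser_off)
        if on is None or off is None:
            raise TraceFileError(
                f"{path}: no laser_on/laser_off for trace {tid!r}: provide "
                "them as arguments or via the .meta.json sidecar")
        roles = group["role"].unique()
        if roles.size != 1:
            raise TraceFileError(f"{path}: trace {tid!r} has mixed roles")
        traces.append(MSTTrace(times=group["time_s"].to_numpy(),
                               intensities=group["intensity"].to_numpy(),
                               laser_on=float(on), laser_off=float(off),
                               trace_id=str(tid), role=str(roles[0]),
                               metadata=info.get("metadata", {})))
    return traces
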