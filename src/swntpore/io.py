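"""File formats: trace CSV / NPZ containers, event TSV, result tables.

Trace CSV layout: ``# key=value`` header lines carrying condition metadata
(sampling_rate_hz is mandatory), then a ``time_s,current_pa`` column header
and one row per sample.  The NPZ container holds the same schema compactly
for large traces.  Events travel as TSV with a stable column set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import CurrentTrace, EventRecord, EventTable, TraceFormatError

__all__ = [
    "write_trace",
    "read_trace",
    "write_trace_npz",
    "read_trace_npz",
    "write_events",
    "read_events",
    "write_json",
]

_REQUIRED_KEY = "sampling_rate_hz"


def _format_meta_value(value: Any) -> str:
    return json.dumps(value) if isinstance(value, str) else repr(value)


def _parse_meta_value(text: str) -> Any:
    try:
        return json.loads(text)
    except (ValueError, TypeError):
        return text


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write a trace as metadata-headed CSV (lossless to float precision)."""
    path = Path(path)
    meta = dict(trace.metadata)
    meta[_REQUIRED_KEY] = trace.sampling_rate
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={_format_meta_value(value)}\n")
        fh.write("time_s,current_pa\n")
        times = trace.times
        for t, c in zip(times, trace.samples):
            fh.write(f"{t:.9g},{c:.9g}\n")
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace CSV written by :func:`write_trace`.

    Raises :class:`TraceFormatError` with a line number for malformed
    headers, a missing sampling rate, or non-uniform timestamps.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" not in body:
                raise TraceFormatError(f"{path}:{lineno}: header line without '='")
            key, _, value = body.partition("=")
            meta[key.strip()] = _parse_meta_value(value.strip())
        elif stripped:
            if stripped != "time_s,current_pa":
                raise TraceFormatError(
                    f"{path}:{lineno}: expected column header 'time_s,current_pa'"
                )
            data_start = lineno
            break
    if _REQUIRED_KEY not in meta:
        raise TraceFormatError(f"{path}: missing required header key {_REQUIRED_KEY}")
    rate = float(meta.pop(_REQUIRED_KEY))
    try:
        arr = np.loadtxt(lines[data_start:], delimiter=",", ndmin=2)
    except ValueError as exc:
        raise TraceFormatError(f"{path}: malformed sample rows: {exc}") from exc
    if arr.shape[0] < 2 or arr.shape[1] != 2:
        raise TraceFormatError(f"{path}: need >= 2 rows of time_s,current_pa")
    dt = np.diff(arr[:, 0])
    if not np.allclose(dt, 1.0 / rate, rtol=1e-6, atol=1e-12):
        bad = int(np.argmax(np.abs(dt - 1.0 / rate))) + data_start + 2
        raise TraceFormatError(f"{path}:{bad}: non-uniform timestamps")
    return CurrentTrace(arr[:, 1], rate, meta)


def write_trace_npz(trace: CurrentTrace, path: str | Path) -> Path:
    """Compact binary container with the same schema as the CSV."""
    path = Path(path)
    np.savez_compressed(
        path,
        samples=trace.samples,
        sampling_rate=np.array([trace.sampling_rate]),
        metadata=np.array([json.dumps(trace.metadata)]),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_trace_npz(path: str | Path) -> CurrentTrace:
    with np.load(path, allow_pickle=False) as archive:
        return CurrentTrace(
            archive["samples"],
            float(archive["sampling_rate"][0]),
            json.loads(str(archive["metadata"][0])),
        )


def write_events(table: EventTable, path: str | Path) -> Path:
    """Write an event table as TSV: event_id, start_s, end_s, dwell_s, pbc_pa."""
    path = Path(path)
    table.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_events(path: str | Path, baseline: float = np.nan) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    required = {"start_s", "end_s", "dwell_s", "pbc_pa"}
    if not required.issubset(df.columns):
        raise TraceFormatError(f"{path}: missing columns {required - set(df.columns)}")
    events = [
        EventRecord(start=r.start_s, end=r.end_s, dwell=r.dwell_s, pbc=r.pbc_pa)
        for r in df.itertuples()
    ]
    return EventTable(events, baseline=baseline)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path
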