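"""CSV readers/writers for sensor logs, events and ground truth.

Sensor log format: header row ``time,ax,ay,az[,gx,gy,gz][,mx,my,mz]
[,pressure][,co]``; time in seconds on a uniform grid, acceleration in m/s^2
or g (declared via config), gyro in rad/s, pressure in hPa, CO in ppm.
Missing optional columns simply disable the detectors that need them.
"""
from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core_signals import GRAVITY_MS2, TIME_GRID_TOL_S, SensorFrame
from .events import DetectionEvent

logger = logging.getLogger(__name__)

_OPTIONAL_GROUPS = (("gx", "gy", "gz"), ("mx", "my", "mz"), ("pressure",), ("co",))


def _parse_axis_map(axis_map: str) -> list[tuple[int, float]]:
    """Parse a remap like ``+x,-z,+y`` into (source index, sign) per output axis."""
    parts = [p.strip() for p in axis_map.split(",")]
    if len(parts) != 3:
        raise ValueError("axis_map must have three components, e.g. '+x,+y,+z'")
    out = []
    for p in parts:
        m = re.fullmatch(r"([+-]?)([xyz])", p)
        if not m:
            raise ValueError(f"bad axis_map component {p!r}")
        sign = -1.0 if m.group(1) == "-" else 1.0
        out.append(("xyz".index(m.group(2)), sign))
    return out


def read_sensor_csv(
    path: str | Path,
    acc_units: str = "ms2",
    axis_map: str = "+x,+y,+z",
) -> SensorFrame | None:
    """Read a sensor log; returns None for an empty file (logged warning).

    The time column must be a uniform grid; the sampling rate is inferred
    from it and non-uniform timestamps are rejected rather than resampled.
    """
    if acc_units not in ("ms2", "g"):
        raise ValueError("acc_units must be 'ms2' or 'g'")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("empty sensor log %s", path)
        return None
    if df.empty:
        logger.warning("sensor log %s has a header but no rows", path)
        return None
    for col in ("time", "ax", "ay", "az"):
        if col not in df.columns:
            raise ValueError(f"sensor log {path} is missing required column {col!r}")

    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        fs = 1.0 / float(np.median(dt))
        if np.any(np.abs(dt - 1.0 / fs) > TIME_GRID_TOL_S):
            raise ValueError(
                f"non-uniform timestamps in {path}; resample explicitly with "
                "resample_linear instead"
            )
    else:
        fs = 1.0

    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if acc_units == "g":
        acc = acc * GRAVITY_MS2
    remap = _parse_axis_map(axis_map)
    acc = np.column_stack([sign * acc[:, src] for src, sign in remap])

    kwargs: dict[str, np.ndarray | None] = {}
    for group in _OPTIONAL_GROUPS:
        present = all(c in df.columns for c in group)
        for c in group:
            kwargs[c] = df[c].to_numpy(dtype=float) if present else None
    return SensorFrame(fs=fs, ax=acc[:, 0], ay=acc[:, 1], az=acc[:, 2], **kwargs)


def write_sensor_csv(frame: SensorFrame, path: str | Path) -> None:
    data: dict[str, np.ndarray] = {"time": frame.t, "ax": frame.ax, "ay": frame.ay, "az": frame.az}
    for name in ("gx", "gy", "gz", "mx", "my", "mz", "pressure", "co"):
        v = getattr(frame, name)
        if v is not None:
            data[name] = v
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def write_events_csv(events: list[DetectionEvent], path: str | Path) -> None:
    rows = [
        {"kind": e.kind, "index": e.index, "time_s": e.time, "detail_json": json.dumps(e.detail)}
        for e in events
    ]
    pd.DataFrame(rows, columns=["kind", "index", "time_s", "detail_json"]).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[DetectionEvent]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    events = []
    for _, row in df.iterrows():
        detail = json.loads(row["detail_json"]) if "detail_json" in df.columns and isinstance(row.get("detail_json"), str) else {}
        events.append(
            DetectionEvent(kind=row["kind"], index=int(row["index"]), time=float(row["time_s"]), detail=detail)
        )
    return events


def write_truth_csv(truth: list[DetectionEvent], path: str | Path) -> None:
    pd.DataFrame(
        [{"kind": e.kind, "index": e.index} for e in truth], columns=["kind", "index"]
    ).to_csv(path, index=False)


def read_truth_csv(path: str | Path, fs: float) -> list[DetectionEvent]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    return [
        DetectionEvent(kind=row["kind"], index=int(row["index"]), time=int(row["index"]) / fs)
        for _, row in df.iterrows()
    ]
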