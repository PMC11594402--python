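"""Signal and event file formats.

Two interchange formats are supported for single-channel signals:

* **CSV** — header ``index,value``, one sample per row.  Lines starting
  with ``#`` are treated as comments (the writers use them to embed the
  generating configuration for provenance).
* **raw int16** — little-endian 16-bit integers, accompanied by a JSON
  sidecar ``<file>.json`` holding ``{"sample_rate": <Hz>, "scale":
  <units per count>}``.  Values are returned as ``counts * scale``.

Detected events travel as CSV with header ``index,peak,threshold``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spike import SpikeEvent, events_to_frame

__all__ = [
    "read_signal",
    "write_signal",
    "read_events",
    "write_events",
    "sidecar_path",
]

_RAW_SUFFIXES = {".raw", ".bin", ".dat", ".i16"}


class SignalFormatError(ValueError):
    """Raised for malformed signal files."""


def sidecar_path(path) -> Path:
    """The JSON metadata file that accompanies a raw int16 signal."""
    return Path(str(path) + ".json")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "raw-int16"):
            raise ValueError(f"unknown signal format {format!r}")
        return format
    if path.suffix.lower() == ".csv":
        return "csv"
    if path.suffix.lower() in _RAW_SUFFIXES:
        return "raw-int16"
    raise ValueError(f"cannot infer signal format from {path.name!r}; pass format=")


def read_signal(path, format: str | None = None) -> np.ndarray:
    """Load a single-channel signal in signal units."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    return _read_raw(path)


def _read_csv(path: Path) -> np.ndarray:
    try:
        frame = pd.read_csv(path, comment="#", header=0,
                            float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise SignalFormatError(f"{path}: {exc}") from exc
    if list(frame.columns[:2]) != ["index", "value"]:
        raise SignalFormatError(
            f"{path}: expected header 'index,value', got {','.join(map(str, frame.columns))}"
        )
    values = pd.to_numeric(frame["value"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        # +2: one for the header row, one for 1-based line numbers
        raise SignalFormatError(
            f"{path}: non-finite or unparseable value at line {int(bad[0]) + 2}"
        )
    return values


def _read_raw(path: Path) -> np.ndarray:
    meta_path = sidecar_path(path)
    if not meta_path.exists():
        raise SignalFormatError(
            f"{path}: raw int16 signals need a JSON sidecar at {meta_path.name}"
        )
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise SignalFormatError(f"{meta_path}: invalid JSON ({exc})") from exc
    for key in ("sample_rate", "scale"):
        if key not in meta:
            raise SignalFormatError(f"{meta_path}: missing required key {key!r}")
    counts = np.fromfile(path, dtype="<i2")
    return counts.astype(float) * float(meta["scale"])


def write_signal(path, samples, format: str | None = None, *,
                 sample_rate: float = 30000.0, scale: float | None = None,
                 comment: str | None = None) -> Path:
    """Write a signal as CSV or raw int16 (+ sidecar); returns the path.

    For raw output, ``scale`` defaults to spanning the int16 range over the
    signal's peak magnitude.  ``comment`` lines are embedded with a ``#``
    prefix in CSV output and stored under ``"comment"`` in the sidecar.
    """
    path = Path(path)
    samples = np.asarray(samples, dtype=float)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w") as fh:
            if comment:
                for line in comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("index,value\n")
            pd.DataFrame({"index": np.arange(samples.size), "value": samples}).to_csv(
                fh, index=False, header=False
            )
        return path
    if scale is None:
        peak = float(np.max(np.abs(samples))) if samples.size else 1.0
        scale = peak / 32000.0 if peak > 0 else 1.0
    counts = np.clip(np.round(samples / scale), -32768, 32767).astype("<i2")
    counts.tofile(path)
    meta = {"sample_rate": sample_rate, "scale": scale}
    if comment:
        meta["comment"] = comment
    sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def write_events(path, events, comment: str | None = None) -> Path:
    """Write detected events as ``index,peak,threshold`` CSV."""
    path = Path(path)
    frame = events_to_frame(events) if not isinstance(events, pd.DataFrame) else events
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
    return path


def read_events(path) -> list[SpikeEvent]:
    """Read an ``index,peak,threshold`` CSV back into event objects."""
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["index", "peak", "threshold"]
    if list(frame.columns[:3]) != expected:
        raise SignalFormatError(f"{path}: expected header {','.join(expected)}")
    return [
        SpikeEvent(int(r["index"]), float(r["peak"]), float(r["threshold"]))
        for _, r in frame.iterrows()
    ]
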