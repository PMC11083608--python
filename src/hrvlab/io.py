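"""Containers and file I/O for ECG records, RR-interval series and analysis reports.

Conventions used throughout the package:

* beat times are seconds from record start (0-based),
* RR intervals are milliseconds,
* an ``RrSeries`` with ``n`` intervals carries ``n + 1`` beat times, so that
  ``beat_times[k+1] - beat_times[k] == intervals[k] / 1000``.

The canonical on-disk formats are deliberately minimal: RR tachograms are
plain text with one interval per line ('#' starts a comment), ECG is CSV with
either one voltage per line or a ``time,voltage`` pair per line, and reports
are JSON (canonical, round-trip exact) or flat CSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "EcgRecord",
    "RrSeries",
    "read_rr_text",
    "write_rr_text",
    "read_ecg_csv",
    "write_ecg_csv",
    "write_report",
    "read_report",
    "register_report",
]

SCHEMA_VERSION = 1


@dataclass
class EcgRecord:
    """Uniformly sampled single-lead ECG voltage series.

    Parameters
    ----------
    samples
        Voltage values in mV; must be finite.
    fs
        Sampling rate in Hz, strictly positive.
    t0
        Start offset in seconds.
    label
        Free-text description.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("ECG record must be a non-empty 1-D series")
        if not np.isfinite(self.samples).all():
            raise ValidationError("ECG samples contain NaN or Inf")
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class RrSeries:
    """Ordered beat-to-beat (RR) interval series.

    ``intervals`` are in ms and strictly positive; ``beat_times`` (seconds)
    has one more entry than ``intervals`` and is strictly increasing.
    ``is_nn`` marks that ectopic/artifact filtering has been applied, i.e.
    the series contains normal-to-normal (NN) intervals.
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    is_nn: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValidationError("RR series must contain at least one interval")
        if not np.isfinite(self.intervals).all():
            raise ValidationError("RR intervals contain NaN or Inf")
        if (self.intervals <= 0).any():
            bad = int(np.argmax(self.intervals <= 0))
            raise ValidationError(
                f"all RR intervals must be > 0 ms; interval {bad} is "
                f"{self.intervals[bad]:g}"
            )
        if self.beat_times.size != self.intervals.size + 1:
            raise ValidationError(
                "beat_times must have exactly one more entry than intervals "
                f"({self.beat_times.size} vs {self.intervals.size})"
            )
        if (np.diff(self.beat_times) <= 0).any():
            raise ValidationError("beat_times must be strictly increasing")
        if not np.allclose(
            np.diff(self.beat_times), self.intervals / 1000.0, rtol=0, atol=1e-9
        ):
            raise ValidationError(
                "beat_times increments disagree with intervals beyond 1e-9 s"
            )

    @classmethod
    def from_intervals(
        cls, intervals_ms: np.ndarray, t0: float = 0.0, is_nn: bool = False,
        label: str = "",
    ) -> "RrSeries":
        """Build a series from intervals alone; beat times are the cumulative sum."""
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        beat_times = t0 + np.concatenate(([0.0], np.cumsum(intervals_ms) / 1000.0))
        return cls(intervals=intervals_ms, beat_times=beat_times, is_nn=is_nn,
                   label=label)

    @property
    def n_intervals(self) -> int:
        return self.intervals.size

    @property
    def duration(self) -> float:
        """Total spanned time in seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def interval_times(self) -> np.ndarray:
        """Time (s) at which each interval *ends* — the tachogram abscissa."""
        return self.beat_times[1:]


# ---------------------------------------------------------------------------
# RR tachogram text format
# ---------------------------------------------------------------------------

def read_rr_text(path: str | Path, units: str = "ms") -> RrSeries:
    """Read an RR tachogram: one interval per line, '#' starts a comment.

    Parameters
    ----------
    path
        Text file with one numeric token per non-comment line.
    units
        ``"ms"`` (default) or ``"s"``; values are converted to ms internally.
    """
    if units not in ("ms", "s"):
        raise ValidationError(f"units must be 'ms' or 's', got {units!r}")
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                value = float(line)
            except ValueError:
                raise ParseError(
                    f"{path.name}, line {lineno}: cannot parse {line!r} as a number"
                ) from None
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{path.name}, line {lineno}: interval must be a positive "
                    f"finite number, got {line!r}"
                )
            values.append(value)
    if not values:
        raise ValidationError(f"{path.name}: no intervals found")
    intervals = np.asarray(values, dtype=float)
    if units == "s":
        intervals = intervals * 1000.0
    return RrSeries.from_intervals(intervals, label=path.stem)


def write_rr_text(rr: RrSeries, path: str | Path) -> None:
    """Write the tachogram in the canonical one-interval-per-line ms format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# RR intervals [ms], n={rr.n_intervals}, is_nn={rr.is_nn}\n")
        for value in rr.intervals:
            fh.write(f"{float(value)!r}\n")


# ---------------------------------------------------------------------------
# ECG CSV format
# ---------------------------------------------------------------------------

def read_ecg_csv(path: str | Path, fs: float) -> EcgRecord:
    """Read ECG from CSV: one voltage per line, or ``time,voltage`` rows.

    The layout is auto-detected from the first data row.  For the two-column
    layout the median time step must agree with ``1/fs`` within 1%.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(
                    f"{path.name}, line {lineno}: cannot parse {line!r}"
                ) from None
    if not rows:
        raise ValidationError(f"{path.name}: empty ECG file")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise FormatError(f"{path.name}: inconsistent column count")
    data = np.asarray(rows, dtype=float)
    if ncol == 1:
        samples = data[:, 0]
        t0 = 0.0
    elif ncol == 2:
        t, samples = data[:, 0], data[:, 1]
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise FormatError(f"{path.name}: time column not increasing")
        if abs(dt - 1.0 / fs) > 0.01 / fs:
            raise FormatError(
                f"{path.name}: time step {dt:g} s inconsistent with fs={fs} Hz "
                f"(expected {1.0 / fs:g} s within 1%)"
            )
        t0 = float(t[0])
    else:
        raise FormatError(f"{path.name}: expected 1 or 2 columns, got {ncol}")
    return EcgRecord(samples=samples, fs=fs, t0=t0, label=path.stem)


def write_ecg_csv(ecg: EcgRecord, path: str | Path, include_time: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if include_time:
            for t, v in zip(ecg.times, ecg.samples):
                fh.write(f"{float(t)!r},{float(v)!r}\n")
        else:
            for v in ecg.samples:
                fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Report serialization (JSON canonical, CSV flat)
# ---------------------------------------------------------------------------

_REPORT_REGISTRY: dict[str, type] = {}


def register_report(cls: type) -> type:
    """Class decorator: make a report dataclass JSON round-trippable."""
    _REPORT_REGISTRY[cls.__name__] = cls
    return cls


def _jsonable(obj: Any) -> Any:
    if obj is None:
        return None
    if isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def report_to_dict(report: Any) -> dict:
    """Flatten a report dataclass into a JSON-ready dict (NaN/Inf become null)."""
    if not dataclasses.is_dataclass(report):
        raise ValidationError(f"not a report dataclass: {type(report).__name__}")
    return {
        "schema_version": SCHEMA_VERSION,
        "report_type": type(report).__name__,
        "data": _jsonable(report),
    }


def write_report(report: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a report bundle to JSON (canonical) or flat CSV.

    JSON round-trips all numeric fields at full ``repr`` precision; non-finite
    values are stored as null.  CSV keeps scalar fields only, one column each
    (a list-of-rows report such as a group-comparison table is written one row
    per entry).
    """
    path = Path(path)
    if format == "json":
        payload = report_to_dict(report)
        try:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
                fh.write("\n")
        except OSError as exc:
            raise IOError(f"cannot write report to {path}: {exc}") from exc
    elif format == "csv":
        frame = report_to_frame(report)
        try:
            frame.to_csv(path, index=False)
        except OSError as exc:
            raise IOError(f"cannot write report to {path}: {exc}") from exc
    else:
        raise ValidationError(f"unknown report format {format!r}")


def report_to_frame(report: Any) -> pd.DataFrame:
    """Flat tabular view of a report: scalar fields only, arrays dropped."""
    if isinstance(report, (list, tuple)):
        return pd.DataFrame([_scalar_fields(r) for r in report])
    return pd.DataFrame([_scalar_fields(report)])


def _scalar_fields(report: Any) -> dict:
    out: dict[str, Any] = {}
    for f in dataclasses.fields(report):
        value = getattr(report, f.name)
        if value is None or isinstance(value, (bool, int, float, str, np.floating,
                                               np.integer)):
            out[f.name] = _jsonable(value)
    return out


def read_report(path: str | Path) -> Any:
    """Reconstruct a report dataclass written by :func:`write_report` (JSON)."""
    with open(path) as fh:
        payload = json.load(fh)
    name = payload.get("report_type")
    cls = _REPORT_REGISTRY.get(name)
    if cls is None:
        raise FormatError(f"unknown report type {name!r} in {path}")
    return _from_dict(cls, payload["data"])


def _from_dict(cls: type, data: dict) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        value = data.get(f.name)
        if isinstance(value, list) and value and not isinstance(value[0], (dict, str)):
            value = np.asarray(value, dtype=float)
        elif isinstance(value, list) and not value:
            value = np.asarray(value, dtype=float)
        elif isinstance(value, dict) and value and all(
            isinstance(k, str) and k.lstrip("-").isdigit() for k in value
        ):
            value = {int(k): v for k, v in value.items()}
        kwargs[f.name] = value
    return cls(**kwargs)
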