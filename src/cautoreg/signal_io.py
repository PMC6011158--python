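"""Reading and writing of two-channel ABP/CBFV recordings and analysis results.

File dialect: comma-separated values with ``#``-prefixed ``key=value``
metadata lines before a single header row naming the columns
(``time,abp,cbfv``; the time column is optional when a sampling rate is
available).  Times are seconds from record start.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "SegmentSelection",
    "read_record",
    "write_record",
    "write_result_json",
    "write_summary_csv",
]

_CONDITIONS = {"baseline", "intervention"}

#: relative tolerance on time-stamp spacing vs. 1/fs
_TIME_TOL_PPM = 1e-6


@dataclass
class SignalRecord:
    """A raw two-channel physiological recording.

    Attributes
    ----------
    time_s : np.ndarray
        Sample times in seconds from record start, strictly increasing.
    abp : np.ndarray
        Arterial blood pressure waveform (mmHg).
    cbfv : np.ndarray
        Cerebral blood-flow velocity waveform (cm/s).
    fs : float
        Sampling rate in Hz.
    meta : dict
        Free-form string metadata (subject id, condition label, ...).
    """

    time_s: np.ndarray
    abp: np.ndarray
    cbfv: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        self.cbfv = np.asarray(self.cbfv, dtype=float)
        n = len(self.time_s)
        if not (len(self.abp) == len(self.cbfv) == n):
            raise ValueError(
                "channel length mismatch: time=%d abp=%d cbfv=%d"
                % (n, len(self.abp), len(self.cbfv))
            )
        if n == 0:
            raise ValueError("empty record")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if n > 1:
            dt = np.diff(self.time_s)
            expected = 1.0 / self.fs
            if np.any(np.abs(dt - expected) > expected * _TIME_TOL_PPM * n):
                raise ValueError("time stamps inconsistent with sampling rate fs")
        cond = self.meta.get("condition")
        if cond is not None and cond not in _CONDITIONS:
            raise ValueError(
                f"condition must be one of {sorted(_CONDITIONS)}, got {cond!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.abp)

    @property
    def duration_s(self) -> float:
        """Record duration counted in whole sample intervals."""
        return self.n_samples / self.fs


@dataclass
class SegmentSelection:
    """A time window into a :class:`SignalRecord`.

    ``duration_s`` defaults to the 5-minute analysis convention.
    """

    start_s: float = 0.0
    duration_s: float = 300.0
    quality_note: str = ""

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError("start_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    def validate_against(self, record: SignalRecord) -> None:
        if self.start_s + self.duration_s > record.duration_s + 0.5 / record.fs:
            raise ValueError(
                "selection [%g, %g) s exceeds record duration %g s"
                % (self.start_s, self.start_s + self.duration_s, record.duration_s)
            )


def read_record(path, fs_override: float | None = None) -> SignalRecord:
    """Read a recording from a delimited text file.

    Metadata lines look like ``# key=value``.  If the file has no time
    column, ``fs_override`` (or an ``fs`` metadata entry) is required and
    the time axis is reconstructed from it.
    """
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                header_lines += 1
                body = stripped.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
            elif stripped:
                break
            else:
                header_lines += 1

    try:
        frame = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    frame.columns = [c.strip().lower() for c in frame.columns]

    for col in ("abp", "cbfv"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
        if not np.issubdtype(frame[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r} of {path}")
        if frame[col].isna().any():
            raise ValueError(f"channel length mismatch: column {col!r} has missing values")

    fs = fs_override
    if fs is None and "fs" in meta:
        fs = float(meta["fs"])

    if "time" in frame.columns:
        if frame["time"].isna().any():
            raise ValueError("channel length mismatch: column 'time' has missing values")
        time_s = frame["time"].to_numpy(dtype=float)
        if fs is None:
            if len(time_s) < 2:
                raise ValueError("cannot infer sampling rate from a single sample")
            fs = 1.0 / float(np.median(np.diff(time_s)))
    else:
        if fs is None:
            raise ValueError(
                f"{path}: no time column and no sampling rate (fs) given; "
                "provide fs_override or an '# fs=' metadata line"
            )
        time_s = np.arange(len(frame)) / fs

    meta.pop("fs", None)
    return SignalRecord(time_s=time_s, abp=frame["abp"].to_numpy(dtype=float),
                        cbfv=frame["cbfv"].to_numpy(dtype=float), fs=float(fs), meta=meta)


def write_record(record: SignalRecord, path) -> Path:
    """Write a record as commented-header CSV at full numeric precision."""
    if record.n_samples == 0:
        raise ValueError("empty record")
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# fs={record.fs!r}\n")
    for key, value in record.meta.items():
        buf.write(f"# {key}={value}\n")
    buf.write("time,abp,cbfv\n")
    data = np.column_stack([record.time_s, record.abp, record.cbfv])
    np.savetxt(buf, data, delimiter=",", fmt="%.17g")
    path.write_text(buf.getvalue())
    return path


def write_result_json(result: dict, path) -> Path:
    """Serialize a nested analysis-result document as JSON."""
    path = Path(path)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    path.write_text(json.dumps(result, indent=2, default=_default, allow_nan=True))
    return path


def write_summary_csv(rows: list[dict], path) -> Path:
    """Write one flat summary row per analyzed segment."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
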