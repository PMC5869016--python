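"""Domain containers and file I/O shared by every analysis stage.

Conventions used throughout the package:

* time in seconds, membrane potential in mV, rates in Hz, currents in pA;
* all intervals (epochs, bins, windows) are half-open ``[onset, offset)`` so
  that a spike falling exactly on an offset belongs to the next interval;
* text tables are comma- or tab-delimited with a one-line header; traces and
  sweep sets live in an HDF5 container (dataset ``samples``/``sweeps``,
  attribute ``fs``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "SpikeTrain",
    "Trace",
    "EpochSet",
    "SweepSet",
    "read_spike_times",
    "write_spike_times",
    "read_trace",
    "write_trace",
    "read_epochs",
    "write_epochs",
    "read_sweeps",
    "write_sweeps",
    "read_table",
    "write_table",
]


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


class ParseError(ValueError):
    """A text input could not be parsed."""


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of a single unit over ``[t_start, t_stop)``."""

    times: np.ndarray
    t_start: float
    t_stop: float
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if not np.all(np.isfinite(times)):
            raise ValidationError("spike times must be finite")
        if times.ndim != 1:
            raise ValidationError("spike times must be one-dimensional")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        if not self.t_stop > self.t_start:
            raise ValidationError("t_stop must exceed t_start")
        if times.size and (times[0] < self.t_start or times[-1] >= self.t_stop):
            raise ValidationError("spike times must lie within [t_start, t_stop)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def firing_rate(self) -> float:
        return self.n_spikes / self.duration

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled membrane potential (mV)."""

    samples: np.ndarray
    fs: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("trace needs at least two samples")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("trace samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_stop(self) -> float:
        return self.t_start + self.duration

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.fs

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (rounded to the grid, clipped to range)."""
        i = int(round((t - self.t_start) * self.fs))
        return min(max(i, 0), self.n_samples - 1)

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open window ``[t0, t1)``."""
        i0 = max(int(np.ceil((t0 - self.t_start) * self.fs - 1e-9)), 0)
        i1 = min(int(np.ceil((t1 - self.t_start) * self.fs - 1e-9)), self.n_samples)
        return self.samples[i0:i1]


@dataclass(frozen=True)
class EpochSet:
    """Non-overlapping light/stimulus intervals, sorted by onset."""

    epochs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float).reshape(-1, 2)
        ep = ep[np.argsort(ep[:, 0])]
        object.__setattr__(self, "epochs", ep)
        if np.any(ep[:, 0] >= ep[:, 1]):
            raise ValidationError("each epoch must satisfy onset < offset")
        if ep.shape[0] > 1 and np.any(ep[1:, 0] < ep[:-1, 1]):
            raise ValidationError("epochs must not overlap")

    def __len__(self) -> int:
        return int(self.epochs.shape[0])

    def __iter__(self):
        return iter(tuple(row) for row in self.epochs)

    @property
    def onsets(self) -> np.ndarray:
        return self.epochs[:, 0]

    @property
    def offsets(self) -> np.ndarray:
        return self.epochs[:, 1]

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any epoch (half-open)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.epochs[:, 0], t, side="right") - 1
        inside = idx >= 0
        ok = np.zeros(t.shape, dtype=bool)
        ok[inside] = t[inside] < self.epochs[idx[inside], 1]
        return ok


@dataclass(frozen=True)
class SweepSet:
    """Stimulus-aligned sweep matrix (one row per sweep) with a condition label per sweep."""

    sweeps: np.ndarray
    fs: float
    stim_times: np.ndarray
    conditions: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sweeps = np.asarray(self.sweeps, dtype=float)
        stim = np.asarray(self.stim_times, dtype=float)
        conditions = list(self.conditions)
        object.__setattr__(self, "sweeps", sweeps)
        object.__setattr__(self, "stim_times", stim)
        object.__setattr__(self, "conditions", conditions)
        if sweeps.ndim != 2:
            raise ValidationError("sweeps must be a 2-D matrix")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if np.any(np.diff(stim) <= 0):
            raise ValidationError("stimulus times must be strictly increasing")
        dur = sweeps.shape[1] / self.fs
        if stim.size and (stim[0] < 0 or stim[-1] >= dur):
            raise ValidationError("stimulus times must fall within the sweep")
        if conditions and len(conditions) != sweeps.shape[0]:
            raise ValidationError("one condition label per sweep required")
        if not conditions:
            object.__setattr__(self, "conditions", [""] * sweeps.shape[0])

    @property
    def n_sweeps(self) -> int:
        return int(self.sweeps.shape[0])

    @property
    def sweep_duration(self) -> float:
        return self.sweeps.shape[1] / self.fs


# --------------------------------------------------------------------------- #
# readers / writers
# --------------------------------------------------------------------------- #

_FLOAT_FMT = "%.12g"
_HEADER_RE = re.compile(r"(\w+)\s*=\s*([-+0-9.eE]+)")


def _data_lines(path: Path):
    """Yield (lineno, stripped-line) for non-blank, non-comment lines; plus header dict."""
    header: dict[str, float] = {}
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for key, val in _HEADER_RE.findall(line):
                header[key] = float(val)
            continue
        rows.append((lineno, line))
    return header, rows


def read_spike_times(path: str | Path, unit_id: str | None = None) -> SpikeTrain:
    """Read spike times from text: one time per line, or ``unit_id,time`` pairs.

    ``t_start``/``t_stop`` come from a ``# t_start=.. t_stop=..`` comment header
    when present, otherwise from the data range (``t_stop`` just past the last
    spike).
    """
    path = Path(path)
    header, rows = _data_lines(path)
    times: list[float] = []
    unit: str | None = None
    skip_header = True
    for lineno, line in rows:
        fields = re.split(r"[,\t\s]+", line)
        if skip_header and any(not _is_number(f) for f in fields[-1:]):
            # a single textual header row ("time" or "unit_id,time") is tolerated
            skip_header = False
            continue
        skip_header = False
        if len(fields) == 1:
            if not _is_number(fields[0]):
                raise ParseError(f"{path}:{lineno}: non-numeric value {fields[0]!r}")
            times.append(float(fields[0]))
        elif len(fields) == 2:
            uid, t = fields
            if not _is_number(t):
                raise ParseError(f"{path}:{lineno}: non-numeric time {t!r}")
            if unit_id is not None and uid != unit_id:
                continue
            if unit is None:
                unit = uid
            elif uid != unit:
                raise ParseError(
                    f"{path}:{lineno}: multiple units present; pass unit_id to select one"
                )
            times.append(float(t))
        else:
            raise ParseError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(fields)}")
    arr = np.asarray(times, dtype=float)
    t_start = header.get("t_start", float(arr[0]) if arr.size else 0.0)
    if "t_stop" in header:
        t_stop = header["t_stop"]
    elif arr.size:
        t_stop = np.nextafter(float(arr[-1]), np.inf)
    else:
        raise ValidationError(f"{path}: empty file without a t_stop header")
    return SpikeTrain(times=arr, t_start=t_start, t_stop=t_stop, unit_id=unit or unit_id or path.stem)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_spike_times(train: SpikeTrain, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# t_start={train.t_start!r} t_stop={train.t_stop!r}", "time"]
    lines += [_FLOAT_FMT % t for t in train.times]
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> Trace:
    """Read a trace from two-column text ``(time, mV)`` or an HDF5 container.

    Text input must be uniformly sampled: the maximum deviation of the time
    increments from their median must stay below 1e-6 of the sample period.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "samples" not in f:
                raise ParseError(f"{path}: missing dataset 'samples'")
            if "fs" not in f["samples"].attrs:
                raise ParseError(f"{path}: missing attribute 'fs'")
            samples = np.asarray(f["samples"][...], dtype=float)
            fs = float(f["samples"].attrs["fs"])
            t_start = float(f["samples"].attrs.get("t_start", 0.0))
        return Trace(samples=samples, fs=fs, t_start=t_start)
    header, rows = _data_lines(path)
    t, v = [], []
    for lineno, line in rows:
        fields = re.split(r"[,\t\s]+", line)
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        if not (_is_number(fields[0]) and _is_number(fields[1])):
            if t:  # numeric rows already seen -> genuine parse failure
                raise ParseError(f"{path}:{lineno}: non-numeric row")
            continue  # header row
        t.append(float(fields[0]))
        v.append(float(fields[1]))
    t_arr = np.asarray(t)
    if t_arr.size < 2:
        raise ValidationError(f"{path}: a trace needs at least two samples")
    dt = np.diff(t_arr)
    period = float(np.median(dt))
    if period <= 0 or np.max(np.abs(dt - period)) > 1e-6 * period:
        raise ValidationError(f"{path}: time column is not uniformly sampled")
    return Trace(samples=np.asarray(v), fs=1.0 / period, t_start=float(t_arr[0]))


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace: HDF5 for ``.h5``/``.hdf5`` paths, two-column text otherwise."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("samples", data=trace.samples)
            ds.attrs["fs"] = trace.fs
            ds.attrs["t_start"] = trace.t_start
        return
    t = trace.times()
    lines = ["time\tmV"]
    lines += [f"{_FLOAT_FMT % ti}\t{_FLOAT_FMT % vi}" for ti, vi in zip(t, trace.samples)]
    path.write_text("\n".join(lines) + "\n")


def read_epochs(path: str | Path, label: str = "") -> EpochSet:
    """Read a two-column onset/offset table (seconds); rows are sorted on read."""
    path = Path(path)
    _, rows = _data_lines(path)
    pairs = []
    for lineno, line in rows:
        fields = re.split(r"[,\t\s]+", line)
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        if not (_is_number(fields[0]) and _is_number(fields[1])):
            if pairs:
                raise ParseError(f"{path}:{lineno}: non-numeric row")
            continue
        pairs.append((float(fields[0]), float(fields[1])))
    return EpochSet(epochs=np.asarray(pairs, dtype=float).reshape(-1, 2), label=label)


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    lines = ["onset\toffset"]
    lines += [f"{_FLOAT_FMT % a}\t{_FLOAT_FMT % b}" for a, b in epochs]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sweeps(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        sweeps = np.asarray(f["sweeps"][...], dtype=float)
        fs = float(f["sweeps"].attrs["fs"])
        stim = np.asarray(f["stim_times"][...], dtype=float)
        if "conditions" in f:
            conditions = [c.decode() if isinstance(c, bytes) else str(c) for c in f["conditions"][...]]
        else:
            conditions = []
    return SweepSet(sweeps=sweeps, fs=fs, stim_times=stim, conditions=conditions)


def write_sweeps(sweeps: SweepSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sweeps", data=sweeps.sweeps)
        ds.attrs["fs"] = sweeps.fs
        f.create_dataset("stim_times", data=sweeps.stim_times)
        f.create_dataset(
            "conditions", data=np.asarray([c.encode() for c in sweeps.conditions])
        )


def write_table(table: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a result table as delimited text; round-trips to full precision.

    Columns must be homogeneous (no mixed text/numeric within a column).
    """
    for col in table.columns:
        if table[col].dtype == object:
            kinds = {type(v) for v in table[col] if v is not None}
            if len({k for k in kinds if k is not str}) and str in kinds:
                raise ValidationError(f"column {col!r} mixes text and numeric values")
    table.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    head = Path(path).read_text(encoding="utf-8").splitlines()
    sep = "\t" if head and "\t" in head[0] else ","
    return pd.read_csv(path, sep=sep)
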