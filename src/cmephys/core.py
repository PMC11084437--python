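"""Domain containers and plain-text/HDF5 I/O shared by every analysis stage.

Conventions used throughout the package:

* time is in seconds, sample indices are 0-based, and analysis windows are
  half-open ``[t_start, t_end)``;
* intracellular voltages are kept as recorded (negative diastole, mV);
* every reported "SD" is the sample standard deviation (n-1 denominator).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "VoltageTrace",
    "BeatSeries",
    "EventKind",
    "ArrhythmiaEvent",
    "CohortTable",
    "read_trace",
    "write_trace",
    "write_results",
    "read_results",
]


class Modality(str, enum.Enum):
    """Recording modality of a trace."""

    AP = "ap"          # intracellular action potential, mV
    MEA = "mea"        # extracellular electrogram, uV
    ECG = "ecg"        # surface/volume-conducted ECG, uV
    CA = "ca"          # fluorescence Ca2+ ratio, dimensionless ratio units


@dataclass(frozen=True)
class VoltageTrace:
    """A uniformly sampled signal.

    The time of sample ``i`` is ``t0_s + i / rate_hz``.
    """

    samples: np.ndarray
    rate_hz: float
    modality: Modality
    t0_s: float = 0.0
    units: str = "mV"
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "modality", Modality(self.modality))
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        bad = np.flatnonzero(~np.isfinite(samples))
        if bad.size:
            raise ValueError(f"non-finite sample at index {bad[0]}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    @property
    def t_end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Nearest sample index for a time, clipped to the trace."""
        i = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), self.n - 1)


@dataclass(frozen=True)
class BeatSeries:
    """Ordered beat (spike / R-wave / transient) times with derived IBIs."""

    beat_times_s: np.ndarray
    source_modality: Modality = Modality.AP

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times_s, dtype=float)
        object.__setattr__(self, "beat_times_s", t)
        object.__setattr__(self, "source_modality", Modality(self.source_modality))
        if t.ndim != 1:
            raise ValueError("beat_times_s must be 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise ValueError(f"beat times not strictly increasing at index {k}")

    @property
    def n_beats(self) -> int:
        return self.beat_times_s.size

    @property
    def ibis_s(self) -> np.ndarray:
        return np.diff(self.beat_times_s)

    def rescaled(self, factor: float) -> "BeatSeries":
        return BeatSeries(self.beat_times_s * factor, self.source_modality)


class EventKind(str, enum.Enum):
    DAD = "DAD"
    OPP = "OPP"
    FAILED_BEAT = "failed_beat"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ArrhythmiaEvent:
    """A typed subthreshold arrhythmogenic event.

    DADs are a single oscillation or a damped run (non-increasing amplitudes
    after the first); OPPs are runs of >= 3 oscillations with strictly
    increasing amplitudes that culminate in an action potential; failed beats
    are subthreshold deflections standing in for an expected beat.
    """

    kind: EventKind
    t_start_s: float
    t_end_s: float
    peak_amplitudes_mv: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))
        object.__setattr__(
            self, "peak_amplitudes_mv", tuple(float(a) for a in self.peak_amplitudes_mv)
        )
        if not self.t_end_s > self.t_start_s:
            raise ValueError("event must have t_end_s > t_start_s")
        amps = self.peak_amplitudes_mv
        if len(amps) < 1:
            raise ValueError("event needs at least one oscillation")
        if self.kind is EventKind.OPP:
            if len(amps) < 3 or not all(b > a for a, b in zip(amps, amps[1:])):
                raise ValueError("OPP requires >= 3 strictly increasing amplitudes")
        if self.kind is EventKind.DAD:
            if any(b > a for a, b in zip(amps[1:], amps[2:])):
                raise ValueError("DAD amplitudes must be non-increasing after the first")

    @property
    def n_oscillations(self) -> int:
        return len(self.peak_amplitudes_mv)


@dataclass
class CohortTable:
    """Per-recording feature rows with group labels.

    The unit of all group statistics: one row per recording/cell, a ``group``
    column drawn from a declared finite label set, and numeric feature columns
    (missing values as NaN).
    """

    data: pd.DataFrame
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        if "group" not in self.data.columns:
            raise ValueError("CohortTable data must have a 'group' column")
        unknown = set(self.data["group"]) - set(self.groups)
        if unknown:
            raise ValueError(f"rows carry undeclared group labels: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]

    def group_values(self, feature: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for g in self.groups:
            v = self.data.loc[self.data["group"] == g, feature].to_numpy(dtype=float)
            out[g] = v[np.isfinite(v)]
        return out


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

_REQUIRED_META = ("rate_hz", "units", "modality")


def write_trace(trace: VoltageTrace, path: str | Path, fmt: str | None = None) -> None:
    """Write a trace as 2-column delimited text (with ``#`` header) or HDF5."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        header = (
            f"# rate_hz={trace.rate_hz!r}\n"
            f"# units={trace.units}\n"
            f"# modality={trace.modality.value}\n"
            f"# t0_s={trace.t0_s!r}\n"
        )
        t = trace.times()
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(f"time_s{sep}value\n")
            for ti, vi in zip(t, trace.samples):
                fh.write(f"{float(ti)!r}{sep}{float(vi)!r}\n")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("samples", data=trace.samples)
            ds.attrs["rate_hz"] = trace.rate_hz
            ds.attrs["units"] = trace.units
            ds.attrs["modality"] = trace.modality.value
            ds.attrs["t0_s"] = trace.t0_s
    else:
        raise ValueError(f"unsupported format: {fmt}")


def read_trace(path: str | Path, fmt: str | None = None) -> VoltageTrace:
    """Read a trace written by :func:`write_trace` (or compatible files).

    Delimited text must carry ``# rate_hz=``, ``# units=``, ``# modality=``
    header comment lines (or a JSON sidecar ``<path>.json`` with those keys)
    and ``time_s,value`` columns.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            ds = fh["samples"]
            attrs = dict(ds.attrs)
            if "rate_hz" not in attrs:
                raise ValueError(f"{path}: missing required attribute rate_hz")
            samples = ds[()]
        return _build_trace(path, samples, attrs)
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unsupported format: {fmt}")
    sep = "," if fmt == "csv" else "\t"
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    if "rate_hz" not in meta:
        raise ValueError(f"{path}: missing required metadata rate_hz")
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    values = df["value"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"{path}: non-finite sample at row index {bad[0]}")
    tcol = df["time_s"].to_numpy(dtype=float)
    if tcol.size >= 2 and not np.all(np.diff(tcol) > 0):
        k = int(np.flatnonzero(np.diff(tcol) <= 0)[0])
        raise ValueError(f"{path}: non-monotone time at row index {k + 1}")
    return _build_trace(path, values, meta)


def _build_trace(path: Path, samples: np.ndarray, meta: Mapping[str, Any]) -> VoltageTrace:
    return VoltageTrace(
        samples=np.asarray(samples, dtype=float),
        rate_hz=float(meta["rate_hz"]),
        modality=Modality(str(meta.get("modality", "ap"))),
        t0_s=float(meta.get("t0_s", 0.0)),
        units=str(meta.get("units", "mV")),
    )


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


# ---------------------------------------------------------------------------
# cohort results
# ---------------------------------------------------------------------------

def write_results(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table as CSV with a per-group mean +/- SD summary block.

    The summary is appended as ``#``-comment lines so the data block
    round-trips through :func:`read_results`. SD uses n-1.
    """
    if len(table.data) == 0:
        raise ValueError("empty cohort table")
    for g in table.groups:
        if not (table.data["group"] == g).any():
            raise ValueError(f"declared group {g!r} has no rows")
    path = Path(path)
    with open(path, "w") as fh:
        table.data.to_csv(fh, index=False)
        fh.write("#\n# summary (mean +/- SD, sample SD)\n")
        for g in table.groups:
            sub = table.data[table.data["group"] == g]
            fh.write(f"# group={g} n={len(sub)}\n")
            for feat in table.feature_names:
                v = sub[feat].to_numpy(dtype=float)
                v = v[np.isfinite(v)]
                if v.size == 0:
                    continue
                sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
                fh.write(f"#   {feat}: {np.mean(v):.6g} +/- {sd:.6g}\n")


def read_results(path: str | Path, groups: Iterable[str] | None = None) -> CohortTable:
    """Read back the data block of a :func:`write_results` file."""
    df = pd.read_csv(path, comment="#")
    groups = tuple(groups) if groups is not None else tuple(dict.fromkeys(df["group"]))
    return CohortTable(df, groups)


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1), the package-wide 'SD'."""
    v = np.asarray(values, dtype=float)
    return float(np.std(v, ddof=1))
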