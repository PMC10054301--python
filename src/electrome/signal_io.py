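"""Reading, writing and light preprocessing of electrome recordings.

Series files are delimited text (CSV or TSV), UTF-8, '.' decimal, with a
header and two required columns:

    time_s, voltage_uV

Times are absolute seconds so files are self-describing; the sampling rate
is re-derived from the median time step on read and checked for uniformity.
Stage schedules are CSV with columns fruit_id, stage, start_day, end_day.
ApEn profiles are TSV (see :mod:`electrome.ripening`).

Readers reject malformed input instead of coercing it, and every error
names the offending column, row or value: for long unattended recordings a
silently repaired file is worse than a refused one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import InvalidInputError

__all__ = [
    "STAGE_ORDER",
    "VoltageSeries",
    "RipeningTrajectory",
    "MissingColumnError",
    "NonMonotoneTimeError",
    "NonUniformSamplingError",
    "read_series",
    "write_series",
    "read_schedules",
    "write_schedules",
    "preprocess",
]

#: Canonical tomato ripening sequence; the recorded experiment spans MG-B-LR.
STAGE_ORDER = ("IMG", "MG", "B", "OR", "LR", "R")

#: Maximum relative jitter tolerated between time steps of a uniform series.
MAX_RELATIVE_JITTER = 1e-6

#: Minimum number of samples any operation leaves behind.
MIN_SAMPLES = 64

_FORMATS = {"csv": ",", "tsv": "\t"}


class MissingColumnError(InvalidInputError):
    pass


class NonMonotoneTimeError(InvalidInputError):
    pass


class NonUniformSamplingError(InvalidInputError):
    pass


@dataclass(frozen=True)
class VoltageSeries:
    """A uniformly sampled micro-voltage recording.

    samples
        Voltage variation in microvolts.
    fs
        Sampling rate in Hz (default 62.5, the acquisition-hardware rate).
    t0
        Recording start offset in seconds; sample k sits at t0 + k/fs.
    fruit_id, channel, stage_at_start
        Provenance metadata.
    """

    samples: np.ndarray
    fs: float = 62.5
    t0: float = 0.0
    fruit_id: str = ""
    channel: int = 0
    stage_at_start: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size < 1:
            raise InvalidInputError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise InvalidInputError(f"non-finite voltage at sample index {bad}")
        if not (self.fs > 0):
            raise InvalidInputError(f"fs must be > 0 Hz, got {self.fs!r}")
        if self.stage_at_start is not None and self.stage_at_start not in STAGE_ORDER:
            raise InvalidInputError(
                f"unknown stage label {self.stage_at_start!r}; expected one of {STAGE_ORDER}"
            )
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def replace(self, **changes) -> "VoltageSeries":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class RipeningTrajectory:
    """Per-fruit stage label as a step function of time in days.

    ``stages`` is an ordered list of (label, start_day, end_day) intervals,
    contiguous and strictly increasing, with labels advancing along the
    canonical ripening sequence IMG < MG < B < OR < LR < R.
    """

    fruit_id: str
    stages: tuple[tuple[str, float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        stages = tuple((str(s), float(a), float(b)) for s, a, b in self.stages)
        if not stages:
            raise InvalidInputError(f"trajectory for {self.fruit_id!r} has no stage intervals")
        prev_rank = -1
        prev_end: float | None = None
        for label, start, end in stages:
            if label not in STAGE_ORDER:
                raise InvalidInputError(f"unknown stage label {label!r} for fruit {self.fruit_id!r}")
            rank = STAGE_ORDER.index(label)
            if rank <= prev_rank:
                raise InvalidInputError(
                    f"stage {label!r} out of ripening order for fruit {self.fruit_id!r}"
                )
            if not (end > start):
                raise InvalidInputError(
                    f"stage {label!r} interval [{start}, {end}) is empty for fruit {self.fruit_id!r}"
                )
            if prev_end is not None and start != prev_end:
                raise InvalidInputError(
                    f"stage intervals not contiguous at day {start} for fruit {self.fruit_id!r}"
                )
            prev_rank, prev_end = rank, end
        object.__setattr__(self, "stages", stages)

    @property
    def start_day(self) -> float:
        return self.stages[0][1]

    @property
    def end_day(self) -> float:
        return self.stages[-1][2]

    @property
    def transition_days(self) -> tuple[float, ...]:
        """Days on which the fruit entered each stage after the first."""
        return tuple(start for _, start, _ in self.stages[1:])

    def stage_at(self, day: float) -> str | None:
        """Stage label covering ``day``, or None outside all intervals."""
        for label, start, end in self.stages:
            if start <= day < end:
                return label
        return None

    def durations(self) -> dict[str, float]:
        return {label: end - start for label, start, end in self.stages}


# ---------------------------------------------------------------------------
# Series files
# ---------------------------------------------------------------------------

def _sep_for(path: Path, format: str | None) -> str:
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if format not in _FORMATS:
        raise InvalidInputError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    return _FORMATS[format]


def read_series(path, format: str | None = None) -> VoltageSeries:
    """Read a voltage series file, validating time-base uniformity.

    The sampling rate is inferred as the reciprocal of the median time step
    and every step is required to agree with it to within a relative jitter
    of 1e-6.
    """
    path = Path(path)
    sep = _sep_for(path, format)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in ("time_s", "voltage_uV"):
        if col not in df.columns:
            raise MissingColumnError(f"{path}: required column {col!r} missing (found {list(df.columns)})")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["voltage_uV"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidInputError(f"{path}: need at least 2 rows to infer a sampling rate")
    if not np.all(np.isfinite(t)):
        raise InvalidInputError(f"{path}: non-finite time at row {int(np.flatnonzero(~np.isfinite(t))[0])}")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError(f"{path}: non-finite voltage at row {int(np.flatnonzero(~np.isfinite(v))[0])}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise NonMonotoneTimeError(f"{path}: time does not strictly increase at row {row}")
    step = float(np.median(dt))
    jitter = float(np.max(np.abs(dt - step)) / step)
    if jitter > MAX_RELATIVE_JITTER:
        row = int(np.argmax(np.abs(dt - step))) + 1
        raise NonUniformSamplingError(
            f"{path}: non-uniform sampling (relative jitter {jitter:.3g} at row {row})"
        )
    meta = {}
    for col, cast in (("fruit_id", str), ("channel", int), ("stage", str)):
        if col in df.columns:
            vals = df[col].unique()
            if len(vals) != 1:
                raise InvalidInputError(f"{path}: metadata column {col!r} is not constant")
            meta["stage_at_start" if col == "stage" else col] = cast(vals[0])
    return VoltageSeries(samples=v, fs=1.0 / step, t0=float(t[0]), **meta)


def write_series(series: VoltageSeries, path, format: str | None = None) -> Path:
    """Write a series as delimited text, round-trippable at double precision."""
    path = Path(path)
    sep = _sep_for(path, format)
    df = pd.DataFrame({"time_s": series.times, "voltage_uV": series.samples})
    if series.fruit_id:
        df["fruit_id"] = series.fruit_id
        df["channel"] = series.channel
    if series.stage_at_start is not None:
        df["stage"] = series.stage_at_start
    df.to_csv(path, sep=sep, index=False, float_format="%.17g", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Stage schedules
# ---------------------------------------------------------------------------

def write_schedules(trajectories, path) -> Path:
    """Write trajectories to a schedules CSV (fruit_id, stage, start_day, end_day)."""
    rows = []
    for traj in trajectories:
        for label, start, end in traj.stages:
            rows.append({"fruit_id": traj.fruit_id, "stage": label, "start_day": start, "end_day": end})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    return Path(path)


def read_schedules(path) -> dict[str, RipeningTrajectory]:
    """Read a schedules CSV into trajectories keyed by fruit id."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = ("fruit_id", "stage", "start_day", "end_day")
    for col in required:
        if col not in df.columns:
            raise MissingColumnError(f"{path}: required column {col!r} missing (found {list(df.columns)})")
    out: dict[str, RipeningTrajectory] = {}
    for fruit_id, grp in df.groupby("fruit_id", sort=False):
        grp = grp.sort_values("start_day")
        stages = tuple(
            (str(r.stage), float(r.start_day), float(r.end_day)) for r in grp.itertuples()
        )
        out[str(fruit_id)] = RipeningTrajectory(fruit_id=str(fruit_id), stages=stages)
    if not out:
        raise InvalidInputError(f"{path}: no schedule rows")
    return out


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    series: VoltageSeries,
    detrend_window_s: float | None = None,
    decimate_by: int | None = None,
) -> VoltageSeries:
    """Optional drift removal, then optional decimation.

    Drift removal subtracts a centered moving average (window truncated at
    the edges) — the software analogue of a slow high-pass stage. Decimation
    keeps every k-th sample and divides fs accordingly; no anti-alias filter
    is applied, so it is intended for already-smooth synthetic signals.
    With both options disabled the function is the identity.
    """
    x = series.samples
    fs = series.fs
    if detrend_window_s is not None:
        if not (detrend_window_s > 0):
            raise InvalidInputError(f"detrend_window_s must be > 0, got {detrend_window_s!r}")
        win = max(1, int(round(detrend_window_s * fs)))
        baseline = (
            pd.Series(x).rolling(window=win, center=True, min_periods=1).mean().to_numpy()
        )
        x = x - baseline
    if decimate_by is not None:
        if not (isinstance(decimate_by, (int, np.integer)) and decimate_by >= 1):
            raise InvalidInputError(f"decimate_by must be an integer >= 1, got {decimate_by!r}")
        if decimate_by > 1:
            x = x[::decimate_by]
            fs = fs / decimate_by
            if x.size < MIN_SAMPLES:
                raise InvalidInputError(
                    f"decimation by {decimate_by} leaves {x.size} samples (< {MIN_SAMPLES})"
                )
    if x is series.samples and fs == series.fs:
        return series
    return series.replace(samples=x, fs=fs)
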