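"""Entropy profiling across ripening: windowed ApEn, stage summaries, dip detection.

The central qualitative phenomenon in ripening fruit electromes is a drop
in signal complexity when the fruit enters the breaker stage, followed by a
partial recovery toward light red. This module makes that testable:

* :func:`windowed_apen` slides a fixed-length window over a recording and
  computes ApEn independently per window (each window's tolerance r comes
  from its own standard deviation, so slow amplitude changes between
  windows do not leak into the regularity estimate);
* :func:`stage_summary` pools windows by the ripening stage covering the
  window midpoint and reports per-stage means;
* :func:`detect_dip` finds the entropy minimum of a smoothed per-fruit
  profile and locates it within the stage schedule;
* :func:`transition_days_summary` recovers the mean and spread of
  stage-to-stage transition times across a cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .complexity import ApEnParams, InvalidInputError, ShortSeriesWarning, apen
from .signal_io import STAGE_ORDER, RipeningTrajectory, VoltageSeries

__all__ = [
    "WindowResult",
    "ApEnProfile",
    "DipReport",
    "StageSummary",
    "windowed_apen",
    "concat_profiles",
    "profile_to_frame",
    "profile_from_frame",
    "stage_summary",
    "detect_dip",
    "transition_days_summary",
]

SECONDS_PER_DAY = 86400.0

#: Default analysis window: 2048 samples (~33 s at 62.5 Hz), non-overlapping.
DEFAULT_WINDOW = 2048

MIN_WINDOW = 64

PROFILE_COLUMNS = ("fruit_id", "window_start_s", "window_end_s", "n_samples", "r_absolute_uV", "apen")


@dataclass(frozen=True)
class WindowResult:
    start_s: float
    end_s: float
    n_samples: int
    r_absolute: float
    apen: float

    @property
    def midpoint_day(self) -> float:
        return 0.5 * (self.start_s + self.end_s) / SECONDS_PER_DAY


@dataclass(frozen=True)
class ApEnProfile:
    """Windowed ApEn values with window positions for one fruit."""

    fruit_id: str
    windows: tuple[WindowResult, ...]
    params: ApEnParams
    window_len_samples: int
    step_samples: int

    @property
    def values(self) -> np.ndarray:
        return np.array([w.apen for w in self.windows])


@dataclass(frozen=True)
class DipReport:
    """Location and depth of the entropy minimum of one fruit's profile."""

    fruit_id: str
    dip_window: tuple[float, float]
    dip_value: float
    pre_dip_median: float | None
    post_dip_median: float | None
    dip_in_stage: str | None = None


@dataclass(frozen=True)
class StageSummary:
    """Per-stage pooled ApEn statistics plus the count of unassignable windows."""

    table: pd.DataFrame
    n_unassigned: int


def windowed_apen(
    series: VoltageSeries,
    params: ApEnParams = ApEnParams(),
    window_len_samples: int = DEFAULT_WINDOW,
    step_samples: int | None = None,
) -> ApEnProfile:
    """ApEn computed independently over sliding windows of one recording.

    Trailing samples that do not fill a whole window are dropped, so the
    window count is floor((N - window_len) / step) + 1. Step defaults to
    the window length (non-overlapping windows).
    """
    if window_len_samples < MIN_WINDOW:
        raise InvalidInputError(f"window_len_samples must be >= {MIN_WINDOW}, got {window_len_samples}")
    if step_samples is None:
        step_samples = window_len_samples
    if step_samples < 1:
        raise InvalidInputError(f"step_samples must be >= 1, got {step_samples}")
    x = series.samples
    n = x.size
    if n < window_len_samples:
        raise InvalidInputError(
            f"series of {n} samples is shorter than one window ({window_len_samples})"
        )
    n_windows = (n - window_len_samples) // step_samples + 1
    windows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortSeriesWarning)
        for k in range(n_windows):
            lo = k * step_samples
            hi = lo + window_len_samples
            res = apen(x[lo:hi], params)
            windows.append(
                WindowResult(
                    start_s=series.t0 + lo / series.fs,
                    end_s=series.t0 + hi / series.fs,
                    n_samples=window_len_samples,
                    r_absolute=res.r_absolute,
                    apen=res.value,
                )
            )
    return ApEnProfile(
        fruit_id=series.fruit_id,
        windows=tuple(windows),
        params=params,
        window_len_samples=window_len_samples,
        step_samples=step_samples,
    )


def concat_profiles(profiles) -> ApEnProfile:
    """Merge per-acquisition profiles of one fruit into one time-ordered profile."""
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("no profiles to concatenate")
    first = profiles[0]
    for p in profiles[1:]:
        if p.fruit_id != first.fruit_id:
            raise InvalidInputError(
                f"cannot concatenate profiles of different fruits ({first.fruit_id!r} vs {p.fruit_id!r})"
            )
        if p.params != first.params or p.window_len_samples != first.window_len_samples:
            raise InvalidInputError("cannot concatenate profiles computed with different parameters")
    windows = tuple(sorted((w for p in profiles for w in p.windows), key=lambda w: w.start_s))
    return ApEnProfile(
        fruit_id=first.fruit_id,
        windows=windows,
        params=first.params,
        window_len_samples=first.window_len_samples,
        step_samples=first.step_samples,
    )


def profile_to_frame(profile: ApEnProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fruit_id": profile.fruit_id,
            "window_start_s": [w.start_s for w in profile.windows],
            "window_end_s": [w.end_s for w in profile.windows],
            "n_samples": [w.n_samples for w in profile.windows],
            "r_absolute_uV": [w.r_absolute for w in profile.windows],
            "apen": [w.apen for w in profile.windows],
        }
    )


def profile_from_frame(df: pd.DataFrame, params: ApEnParams = ApEnParams()) -> list[ApEnProfile]:
    """Rebuild per-fruit profiles from a profile table (TSV round-trip)."""
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"profile table missing column {col!r}")
    out = []
    for fruit_id, grp in df.groupby("fruit_id", sort=False):
        grp = grp.sort_values("window_start_s")
        windows = tuple(
            WindowResult(
                start_s=float(r.window_start_s),
                end_s=float(r.window_end_s),
                n_samples=int(r.n_samples),
                r_absolute=float(r.r_absolute_uV),
                apen=float(r.apen),
            )
            for r in grp.itertuples()
        )
        n = windows[0].n_samples
        step = n
        if len(windows) > 1:
            dt = windows[1].start_s - windows[0].start_s
            fs = n / (windows[0].end_s - windows[0].start_s)
            step = max(1, int(round(dt * fs)))
        out.append(
            ApEnProfile(
                fruit_id=str(fruit_id),
                windows=windows,
                params=params,
                window_len_samples=n,
                step_samples=step,
            )
        )
    return out


def stage_summary(profiles, trajectories: dict[str, RipeningTrajectory]) -> StageSummary:
    """Pool windows within ripening stages across fruits.

    Each window is assigned to the stage covering its midpoint (in days);
    windows whose midpoint falls outside every stage interval are counted
    as unassigned rather than silently dropped. Mean and SD are over all
    assigned windows pooled within the stage (SD with ddof=0).
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("stage_summary needs at least one profile")
    rows = []
    n_unassigned = 0
    for p in profiles:
        if p.fruit_id not in trajectories:
            raise InvalidInputError(f"no trajectory for fruit {p.fruit_id!r}")
        traj = trajectories[p.fruit_id]
        for w in p.windows:
            stage = traj.stage_at(w.midpoint_day)
            if stage is None:
                n_unassigned += 1
            else:
                rows.append({"stage": stage, "fruit_id": p.fruit_id, "apen": w.apen})
    if not rows:
        raise InvalidInputError("no window could be assigned to a stage")
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("stage")
        .agg(
            mean_apen=("apen", "mean"),
            sd_apen=("apen", lambda v: float(np.std(v, ddof=0))),
            n_windows=("apen", "size"),
            n_fruits=("fruit_id", "nunique"),
        )
        .reset_index()
    )
    agg["__rank"] = agg["stage"].map(STAGE_ORDER.index)
    agg = agg.sort_values("__rank").drop(columns="__rank").reset_index(drop=True)
    return StageSummary(table=agg, n_unassigned=n_unassigned)


def _running_median(values: np.ndarray, k: int) -> np.ndarray:
    return (
        pd.Series(values).rolling(window=k, center=True, min_periods=1).median().to_numpy()
    )


def detect_dip(
    profile: ApEnProfile,
    smooth_k: int = 5,
    trajectory: RipeningTrajectory | None = None,
) -> DipReport:
    """Locate the entropy dip of one fruit's profile.

    The profile is smoothed with a running median (window ``smooth_k``,
    truncated at the edges) to resist spike-window outliers; the dip is the
    global minimum of the smoothed curve, ties broken toward the earliest
    window. Pre/post medians are over the smoothed values strictly before
    and after the dip window; a median over an empty side is reported as
    None. When a trajectory is supplied the stage covering the dip window's
    midpoint is reported.
    """
    if smooth_k < 1 or smooth_k % 2 == 0:
        raise InvalidInputError(f"smooth_k must be a positive odd integer, got {smooth_k}")
    values = profile.values
    if values.size < 2 * smooth_k:
        raise InvalidInputError(
            f"profile has {values.size} windows; need at least {2 * smooth_k} for smooth_k={smooth_k}"
        )
    smoothed = _running_median(values, smooth_k)
    i = int(np.argmin(smoothed))  # argmin returns the earliest tie
    dip_window = profile.windows[i]
    pre = float(np.median(smoothed[:i])) if i > 0 else None
    post = float(np.median(smoothed[i + 1 :])) if i < values.size - 1 else None
    stage = trajectory.stage_at(dip_window.midpoint_day) if trajectory is not None else None
    return DipReport(
        fruit_id=profile.fruit_id,
        dip_window=(dip_window.start_s, dip_window.end_s),
        dip_value=float(smoothed[i]),
        pre_dip_median=pre,
        post_dip_median=post,
        dip_in_stage=stage,
    )


def transition_days_summary(trajectories) -> pd.DataFrame:
    """Mean and SD (ddof=0) of days spent in each stage before transitioning.

    Rows are consecutive stage pairs ("MG->B"): the interval length is the
    duration of the earlier stage, aggregated across fruits that exhibit
    that transition.
    """
    trajs = list(trajectories.values()) if isinstance(trajectories, dict) else list(trajectories)
    if not trajs:
        raise InvalidInputError("transition_days_summary needs at least one trajectory")
    spans: dict[tuple[str, str], list[float]] = {}
    for traj in trajs:
        for (s1, a1, b1), (s2, _, _) in zip(traj.stages, traj.stages[1:]):
            spans.setdefault((s1, s2), []).append(b1 - a1)
    rows = [
        {
            "transition": f"{s1}->{s2}",
            "mean_days": float(np.mean(v)),
            "sd_days": float(np.std(v, ddof=0)),
            "n_fruits": len(v),
        }
        for (s1, s2), v in spans.items()
    ]
    rows.sort(key=lambda r: STAGE_ORDER.index(r["transition"].split("->")[0]))
    return pd.DataFrame(rows)
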