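"""Seeded synthetic fruit-electrome cohorts with stage-dependent regularity.

No public micro-voltage recordings of ripening fruit exist, so this module
generates labeled stand-ins whose *statistical regularity* varies by
ripening stage the way the analysis assumes: high signal complexity at
mature green (MG), a marked drop at breaker (B), partial recovery at light
red (LR).

The regularity dial is the classic MIX(p) family: a deterministic period-12
sinusoid in which each sample is independently replaced, with probability
p, by an iid uniform draw of matching variance,

    x_j = sqrt(2) sin(2 pi j / 12),   y_j ~ U(-sqrt(3), sqrt(3)),
    out_j = (1 - z_j) x_j + z_j y_j,  z_j ~ Bernoulli(p).

Expected ApEn increases monotonically with p, and the marginal variance is
~1 for every p, so the stages differ in temporal structure rather than in
amplitude. On top of the MIX backbone each acquisition carries a linear
baseline drift and sparse Poisson-timed biphasic spikes emulating transient
depolarization-like deflections.

All randomness flows from one master seed through numpy SeedSequence
spawning keyed on (master_seed, fruit index, day index): cohorts regenerate
byte-identically, and distinct fruits and days use independent streams.
Stage durations are drawn per fruit, so every fruit shows its own
transition days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complexity import InvalidInputError
from .signal_io import MIN_SAMPLES, RipeningTrajectory, VoltageSeries

__all__ = [
    "StageSignalSpec",
    "CohortConfig",
    "Cohort",
    "DEFAULT_STAGE_SPECS",
    "DEFAULT_STAGE_DURATIONS",
    "mix_process",
    "simulate_acquisition",
    "simulate_trajectories",
    "simulate_cohort",
]

_SIN_AMPLITUDE = np.sqrt(2.0)
_UNIFORM_HALF_WIDTH = np.sqrt(3.0)
_MIX_PERIOD = 12


@dataclass(frozen=True)
class StageSignalSpec:
    """Signal model of one ripening stage.

    mix_p
        Irregularity fraction of the MIX process in [0, 1]; higher means
        more complex (higher expected ApEn).
    amplitude_uV
        Scale applied to the unit-variance MIX backbone.
    drift_uV_per_hour
        Slope of the slow linear baseline drift.
    spike_rate_per_hour, spike_amplitude_uV
        Rate and size of biphasic one-sample spikes (one positive then one
        negative deflection), Poisson-timed.
    """

    stage: str
    mix_p: float
    amplitude_uV: float = 50.0
    drift_uV_per_hour: float = 30.0
    spike_rate_per_hour: float = 2.0
    spike_amplitude_uV: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mix_p <= 1.0):
            raise InvalidInputError(f"mix_p must be in [0, 1], got {self.mix_p!r}")
        if not (self.amplitude_uV > 0):
            raise InvalidInputError(f"amplitude_uV must be > 0, got {self.amplitude_uV!r}")
        if self.spike_rate_per_hour < 0:
            raise InvalidInputError(f"spike_rate_per_hour must be >= 0, got {self.spike_rate_per_hour!r}")
        if not (self.spike_amplitude_uV > 0):
            raise InvalidInputError(f"spike_amplitude_uV must be > 0, got {self.spike_amplitude_uV!r}")


# Stage irregularity chosen to reproduce the observed ripening pattern
# qualitatively — only the ordering MG > B and LR > B is treated as ground
# truth, since no absolute ApEn levels are reported for real fruit.
DEFAULT_STAGE_SPECS: dict[str, StageSignalSpec] = {
    "MG": StageSignalSpec(stage="MG", mix_p=0.6),
    "B": StageSignalSpec(stage="B", mix_p=0.2),
    "LR": StageSignalSpec(stage="LR", mix_p=0.5),
}

#: (mean, SD) of stage duration in days, truncated positive.
DEFAULT_STAGE_DURATIONS: dict[str, tuple[float, float]] = {
    "MG": (4.0, 1.0),
    "B": (3.0, 1.0),
    "LR": (2.0, 0.5),
}


@dataclass(frozen=True)
class CohortConfig:
    """Simulator settings for a cohort of fruits.

    Defaults mirror the recorded experiment's design: five repetitions of
    four fruits (20 fruits), one acquisition per day at 62.5 Hz, stages
    MG -> B -> LR. ``seconds_per_day`` compresses each simulated day's
    acquisition to a desk-scale duration (default 20 min of samples per
    day); pass 86400 for full 24 h acquisitions.
    """

    n_fruits: int = 20
    stage_specs: dict[str, StageSignalSpec] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_SPECS)
    )
    stage_duration_days: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DURATIONS)
    )
    fs: float = 62.5
    seconds_per_day: float = 1200.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_fruits, (int, np.integer)) and self.n_fruits >= 1):
            raise InvalidInputError(f"n_fruits must be a positive integer, got {self.n_fruits!r}")
        if not (self.fs > 0):
            raise InvalidInputError(f"fs must be > 0, got {self.fs!r}")
        if self.seconds_per_day * self.fs < MIN_SAMPLES:
            raise InvalidInputError(
                f"seconds_per_day={self.seconds_per_day} at fs={self.fs} yields "
                f"fewer than {MIN_SAMPLES} samples per acquisition"
            )
        for stage in self.stage_duration_days:
            mean, sd = self.stage_duration_days[stage]
            if not (mean > 0) or sd < 0:
                raise InvalidInputError(
                    f"stage {stage!r} duration (mean={mean}, sd={sd}) must have mean > 0, sd >= 0"
                )
        for stage, spec in self.stage_specs.items():
            if stage not in self.stage_duration_days:
                raise InvalidInputError(f"stage {stage!r} has a signal spec but no duration")
        for stage in self.stage_duration_days:
            if stage not in self.stage_specs:
                raise InvalidInputError(f"stage {stage!r} has a duration but no signal spec")

    @property
    def stages(self) -> tuple[str, ...]:
        from .signal_io import STAGE_ORDER

        return tuple(s for s in STAGE_ORDER if s in self.stage_specs)

    def to_dict(self) -> dict:
        return {
            "n_fruits": self.n_fruits,
            "fs": self.fs,
            "seconds_per_day": self.seconds_per_day,
            "master_seed": self.master_seed,
            "stage_specs": {
                s: {
                    "mix_p": spec.mix_p,
                    "amplitude_uV": spec.amplitude_uV,
                    "drift_uV_per_hour": spec.drift_uV_per_hour,
                    "spike_rate_per_hour": spec.spike_rate_per_hour,
                    "spike_amplitude_uV": spec.spike_amplitude_uV,
                }
                for s, spec in self.stage_specs.items()
            },
            "stage_duration_days": {
                s: list(v) for s, v in self.stage_duration_days.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        if "stage_specs" in kwargs:
            kwargs["stage_specs"] = {
                s: StageSignalSpec(stage=s, **spec) for s, spec in kwargs["stage_specs"].items()
            }
        if "stage_duration_days" in kwargs:
            kwargs["stage_duration_days"] = {
                s: (float(v[0]), float(v[1])) for s, v in kwargs["stage_duration_days"].items()
            }
        return cls(**kwargs)


@dataclass(frozen=True)
class Cohort:
    """Simulated recordings (one VoltageSeries per fruit-day) plus trajectories."""

    series: tuple[VoltageSeries, ...]
    trajectories: dict[str, RipeningTrajectory]
    config: CohortConfig


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), *key)))


def mix_process(n: int, p: float, seed) -> np.ndarray:
    """MIX(p) sequence of length n: sinusoid with iid-uniform replacements.

    Deterministic given (n, p, seed); ``seed`` may be an int or a Generator.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise InvalidInputError(f"n must be a positive integer, got {n!r}")
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"p must be in [0, 1], got {p!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    j = np.arange(n)
    x = _SIN_AMPLITUDE * np.sin(2.0 * np.pi * j / _MIX_PERIOD)
    z = rng.random(n) < p
    y = rng.uniform(-_UNIFORM_HALF_WIDTH, _UNIFORM_HALF_WIDTH, n)
    return np.where(z, y, x)


def simulate_acquisition(
    fruit_id: str,
    stage: str,
    spec: StageSignalSpec,
    duration_s: float,
    fs: float = 62.5,
    seed=0,
    t0: float = 0.0,
) -> VoltageSeries:
    """One acquisition: scaled MIX backbone + linear drift + biphasic spikes."""
    n = int(np.ceil(duration_s * fs))
    if n < MIN_SAMPLES:
        raise InvalidInputError(
            f"acquisition of {duration_s} s at {fs} Hz has {n} samples (< {MIN_SAMPLES})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = spec.amplitude_uV * mix_process(n, spec.mix_p, rng)
    t_hours = np.arange(n) / fs / 3600.0
    v = v + spec.drift_uV_per_hour * t_hours
    n_spikes = rng.poisson(spec.spike_rate_per_hour * duration_s / 3600.0)
    if n_spikes > 0:
        # Biphasic: one positive sample immediately followed by one negative.
        idx = rng.integers(0, n - 1, size=n_spikes)
        v = v.copy()
        np.add.at(v, idx, spec.spike_amplitude_uV)
        np.add.at(v, idx + 1, -spec.spike_amplitude_uV)
    return VoltageSeries(samples=v, fs=fs, t0=t0, fruit_id=fruit_id, stage_at_start=stage)


def _draw_durations(config: CohortConfig, rng: np.random.Generator) -> dict[str, int]:
    """Truncated-positive normal stage durations, rounded to whole days >= 1."""
    out: dict[str, int] = {}
    for stage in config.stages:
        mean, sd = config.stage_duration_days[stage]
        d = rng.normal(mean, sd)
        while d <= 0:
            d = rng.normal(mean, sd)
        out[stage] = max(1, int(round(d)))
    return out


def simulate_trajectories(config: CohortConfig) -> dict[str, RipeningTrajectory]:
    """Per-fruit stage schedules only (no signals); same draws as the cohort."""
    trajectories: dict[str, RipeningTrajectory] = {}
    for i in range(config.n_fruits):
        fruit_id = f"fruit{i:02d}"
        durations = _draw_durations(config, _rng(config.master_seed, i))
        stages = []
        day = 0.0
        for stage in config.stages:
            stages.append((stage, day, day + durations[stage]))
            day += durations[stage]
        trajectories[fruit_id] = RipeningTrajectory(fruit_id=fruit_id, stages=tuple(stages))
    return trajectories


def simulate_cohort(config: CohortConfig) -> Cohort:
    """A full labeled cohort: one acquisition per fruit per simulated day.

    Acquisition d of a fruit starts at t0 = d * 86400 s (day-aligned clock)
    and contains ``seconds_per_day`` seconds of samples, so window times map
    onto trajectory days directly. Stage-duration draws use the per-fruit
    stream and signal draws the per-(fruit, day) stream, which makes the
    trajectories independent of ``seconds_per_day``.
    """
    trajectories = simulate_trajectories(config)
    series: list[VoltageSeries] = []
    for i in range(config.n_fruits):
        fruit_id = f"fruit{i:02d}"
        traj = trajectories[fruit_id]
        for day in range(int(traj.end_day)):
            stage = traj.stage_at(day + 0.5)
            assert stage is not None
            series.append(
                simulate_acquisition(
                    fruit_id=fruit_id,
                    stage=stage,
                    spec=config.stage_specs[stage],
                    duration_s=config.seconds_per_day,
                    fs=config.fs,
                    seed=_rng(config.master_seed, i, day),
                    t0=day * 86400.0,
                )
            )
    return Cohort(series=tuple(series), trajectories=trajectories, config=config)
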