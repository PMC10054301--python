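import numpy as np
import pytest

from electrome import CohortConfig, VoltageSeries, simulate_cohort

#: Desk-scale cohort settings reused across tests: 120 s of samples per
#: simulated day keeps a full 20-fruit multi-day cohort cheap while leaving
#: >10 analysis windows of 512 samples per acquisition.
DESK_SECONDS_PER_DAY = 120.0
DESK_WINDOW = 512


def desk_config(seed: int, **overrides) -> CohortConfig:
    kwargs = dict(master_seed=seed, seconds_per_day=DESK_SECONDS_PER_DAY)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-fruit desk-scale cohort shared by tests that only read it."""
    return simulate_cohort(desk_config(seed=11, n_fruits=6))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_series(samples, fs=62.5, **kwargs) -> VoltageSeries:
    return VoltageSeries(samples=np.asarray(samples, dtype=float), fs=fs, **kwargs)


def logistic_map(n: int, x0: float = 0.3) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x
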