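"""Approximate entropy (ApEn) of micro-voltage time series.

ApEn(m, r) = phi^m(r) - phi^(m+1)(r), where

    phi^m(r) = mean_i ln( C_i^m(r) ),
    C_i^m(r) = (# of m-vectors within distance r of template i) / (N - m + 1),

with templates the N - m + 1 overlapping vectors of m consecutive samples.
Low values indicate repetitive, predictable signals; high values irregular
ones.  Defaults follow the standard choice for electrome recordings:
m = 2 and r = 0.2 times the standard deviation of the analyzed series.

Two distance metrics are supported.  The Chebyshev (maximum) norm is the
default, matching Pincus's original formulation; the Euclidean norm is
offered as a first-class alternative because parts of the electrophysiology
literature describe the match rule in Euclidean terms.  A distance exactly
equal to r counts as a match (the rule is "less or equal").

The module is pure computation: no file I/O, no global state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ApEnParams",
    "ApEnResult",
    "InvalidInputError",
    "UnmatchedTemplateError",
    "OracleSizeError",
    "ShortSeriesWarning",
    "embed",
    "tolerance_from_series",
    "phi",
    "apen",
    "apen_oracle",
]

METRICS = ("chebyshev", "euclidean")

#: Below this many samples ApEn is noticeably biased; a warning is emitted.
SHORT_SERIES_N = 50

#: Hard size guard for the quadratic reference implementation.
ORACLE_MAX_N = 2000

#: Template chunk size for the memory-bounded fast path.
_CHUNK = 2048


class InvalidInputError(ValueError):
    """Raised when an input violates a precondition."""


class UnmatchedTemplateError(InvalidInputError):
    """Raised when self-matches are excluded and a template matches nothing."""

    def __init__(self, template_index: int):
        self.template_index = template_index
        super().__init__(
            f"template vector {template_index} has no match within tolerance; "
            "log of zero is undefined (self_match=False)"
        )


class OracleSizeError(InvalidInputError):
    """Raised when the brute-force oracle is asked to exceed its size guard."""


class ShortSeriesWarning(UserWarning):
    """ApEn on short series carries substantial small-sample bias."""


@dataclass(frozen=True)
class ApEnParams:
    """Parameters of the ApEn statistic.

    m
        Embedding dimension: length of the template vectors. Default 2.
    r_factor
        Tolerance as a fraction of the population standard deviation of the
        series being analyzed. Default 0.2.
    metric
        "chebyshev" (max norm, default) or "euclidean".
    self_match
        Include the template itself among its matches (default True). This
        guarantees finite logarithms and ApEn >= 0.
    """

    m: int = 2
    r_factor: float = 0.2
    metric: str = "chebyshev"
    self_match: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise InvalidInputError(f"embedding dimension m must be a positive integer, got {self.m!r}")
        if not (self.r_factor > 0):
            raise InvalidInputError(f"r_factor must be > 0, got {self.r_factor!r}")
        if self.metric not in METRICS:
            raise InvalidInputError(f"metric must be one of {METRICS}, got {self.metric!r}")


@dataclass(frozen=True)
class ApEnResult:
    """ApEn value (nats) together with the quantities it is built from."""

    value: float
    n_samples: int
    r_absolute: float
    phi_m: float
    phi_m_plus_1: float


def _as_series(series, *, name: str = "series") -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {x.shape}")
    if x.size == 0:
        raise InvalidInputError(f"{name} is empty")
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise InvalidInputError(f"{name} contains a non-finite value at index {bad}")
    return x


def embed(series, m: int) -> np.ndarray:
    """All N - m + 1 overlapping m-dimensional template vectors.

    Vector i (0-based) is (x_i, ..., x_{i+m-1}).
    """
    x = _as_series(series)
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise InvalidInputError(f"m must be a positive integer, got {m!r}")
    n = x.size
    if n <= m + 1:
        raise InvalidInputError(
            f"series of length N={n} is too short to embed at m={m}; need N >= m + 2"
        )
    return np.lib.stride_tricks.sliding_window_view(x, m).copy()


def tolerance_from_series(series, r_factor: float) -> float:
    """Absolute tolerance r = r_factor x population SD of the series.

    A constant series has SD 0 and maps to r = 0; with the inclusive match
    rule identical vectors (distance 0 <= 0) still match, so ApEn of a
    constant series is exactly 0 rather than an error.
    """
    x = _as_series(series)
    if not (r_factor > 0):
        raise InvalidInputError(f"r_factor must be > 0, got {r_factor!r}")
    return float(r_factor * x.std(ddof=0))


def phi(series, m: int, r_absolute: float, metric: str = "chebyshev", self_match: bool = True) -> float:
    """phi^m(r): mean over templates of ln(fraction of vectors within r).

    The match rule is inclusive: distance == r counts. With self_match every
    C_i >= 1/(N-m+1), so the logarithm is always finite.
    """
    if r_absolute < 0:
        raise InvalidInputError(f"r_absolute must be >= 0, got {r_absolute!r}")
    if metric not in METRICS:
        raise InvalidInputError(f"metric must be one of {METRICS}, got {metric!r}")
    vectors = embed(series, m)
    n_vec = vectors.shape[0]
    log_c = np.empty(n_vec)
    # Chunked template loop keeps peak memory at _CHUNK x n_vec distances.
    for lo in range(0, n_vec, _CHUNK):
        hi = min(lo + _CHUNK, n_vec)
        d = cdist(vectors[lo:hi], vectors, metric=metric)
        counts = np.count_nonzero(d <= r_absolute, axis=1)
        if not self_match:
            counts = counts - 1
            if np.any(counts == 0):
                raise UnmatchedTemplateError(lo + int(np.flatnonzero(counts == 0)[0]))
        log_c[lo:hi] = np.log(counts / n_vec)
    return float(log_c.mean())


def apen(series, params: ApEnParams = ApEnParams()) -> ApEnResult:
    """ApEn(m, r) of a series, with r fixed once from this exact series.

    Windowed callers therefore get a per-window tolerance: each window's r
    is 0.2 (by default) of that window's own standard deviation.
    """
    x = _as_series(series)
    n = x.size
    if n < params.m + 3:
        raise InvalidInputError(
            f"series of length N={n} is too short for ApEn at m={params.m}; need N >= m + 3"
        )
    if n < SHORT_SERIES_N:
        warnings.warn(
            f"ApEn on N={n} samples is biased (N < {SHORT_SERIES_N})",
            ShortSeriesWarning,
            stacklevel=2,
        )
    r = tolerance_from_series(x, params.r_factor)
    phi_m = phi(x, params.m, r, params.metric, params.self_match)
    phi_m1 = phi(x, params.m + 1, r, params.metric, params.self_match)
    return ApEnResult(
        value=phi_m - phi_m1,
        n_samples=n,
        r_absolute=r,
        phi_m=phi_m,
        phi_m_plus_1=phi_m1,
    )


# ---------------------------------------------------------------------------
# Reference implementation
# ---------------------------------------------------------------------------

def _phi_reference(x: np.ndarray, m: int, r: float, metric: str, self_match: bool) -> float:
    """Template-by-template transliteration of the phi^m(r) definition."""
    n_vec = x.size - m + 1
    vectors = [x[i : i + m] for i in range(n_vec)]
    total = 0.0
    for i, v in enumerate(vectors):
        if metric == "chebyshev":
            dists = np.max(np.abs(np.stack(vectors) - v), axis=1)
        else:
            dists = np.sqrt(np.sum((np.stack(vectors) - v) ** 2, axis=1))
        count = int(np.count_nonzero(dists <= r))
        if not self_match:
            count -= 1
            if count == 0:
                raise UnmatchedTemplateError(i)
        total += math.log(count / n_vec)
    return total / n_vec


def apen_oracle(series, params: ApEnParams = ApEnParams()) -> ApEnResult:
    """Brute-force ApEn for verification: no shortcuts, quadratic cost.

    Guarded at N <= 2000; agrees with :func:`apen` to ~1e-10 by construction
    up to floating-point summation order.
    """
    x = _as_series(series)
    n = x.size
    if n > ORACLE_MAX_N:
        raise OracleSizeError(f"oracle refuses N={n} > {ORACLE_MAX_N} (quadratic cost guard)")
    if n < params.m + 3:
        raise InvalidInputError(
            f"series of length N={n} is too short for ApEn at m={params.m}; need N >= m + 3"
        )
    r = params.r_factor * float(np.std(x, ddof=0))
    phi_m = _phi_reference(x, params.m, r, params.metric, params.self_match)
    phi_m1 = _phi_reference(x, params.m + 1, r, params.metric, params.self_match)
    return ApEnResult(
        value=phi_m - phi_m1,
        n_samples=n,
        r_absolute=r,
        phi_m=phi_m,
        phi_m_plus_1=phi_m1,
    )
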