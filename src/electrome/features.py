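"""Per-window feature extraction and nearest-centroid stage classification.

ApEn is the headline feature; five simple descriptive statistics ride
along so its discriminative value can be compared against cheaper
alternatives:

    apen                       windowed approximate entropy
    sd_uV                      population standard deviation
    skewness                   standardized third central moment
    excess_kurtosis            standardized fourth central moment - 3
    mean_abs_successive_diff   mean |x_{k+1} - x_k|
    lag1_autocorrelation       Pearson correlation of (x_k, x_{k+1})

Constant windows take the degenerate value 0 for the standardized moments
and the autocorrelation.

The classifier is a deterministic nearest-centroid rule in a robustly
standardized feature space (global per-feature median and IQR), so any
affine rescaling of a raw feature leaves predictions unchanged. Splits for
evaluation should always be by fruit, never by window: adjacent windows of
one recording are not independent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import ApEnParams, InvalidInputError, ShortSeriesWarning, apen
from .signal_io import STAGE_ORDER, VoltageSeries
from .ripening import MIN_WINDOW

__all__ = [
    "FEATURE_NAMES",
    "CentroidModel",
    "ClassificationResult",
    "extract_features",
    "window_features",
    "fit_centroids",
    "classify",
]

FEATURE_NAMES = (
    "apen",
    "sd_uV",
    "skewness",
    "excess_kurtosis",
    "mean_abs_successive_diff",
    "lag1_autocorrelation",
)


def window_features(x: np.ndarray, params: ApEnParams = ApEnParams()) -> dict[str, float]:
    """The six features of one window of samples."""
    x = np.asarray(x, dtype=float)
    # exact constancy check: summation rounding can leave SD ~1e-16 on a
    # constant window, which would blow up the standardized moments
    if np.all(x == x[0]):
        sd = skew = kurt = ac1 = 0.0
    else:
        sd = float(np.std(x, ddof=0))
        z = (x - x.mean()) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
        a, b = x[:-1], x[1:]
        denom = float(np.std(a, ddof=0) * np.std(b, ddof=0))
        if denom == 0.0:
            ac1 = 0.0
        else:
            ac1 = float(np.mean((a - a.mean()) * (b - b.mean())) / denom)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortSeriesWarning)
        apen_value = apen(x, params).value
    return {
        "apen": apen_value,
        "sd_uV": sd,
        "skewness": skew,
        "excess_kurtosis": kurt,
        "mean_abs_successive_diff": float(np.mean(np.abs(np.diff(x)))),
        "lag1_autocorrelation": ac1,
    }


def extract_features(
    series: VoltageSeries,
    window_len_samples: int,
    step_samples: int | None = None,
    params: ApEnParams = ApEnParams(),
) -> pd.DataFrame:
    """Feature table with one row per window of one recording.

    Rows align one-to-one with the windows of
    :func:`electrome.ripening.windowed_apen` at the same geometry. The
    stage column is the recording's stage label when known.
    """
    if window_len_samples < MIN_WINDOW:
        raise InvalidInputError(f"window_len_samples must be >= {MIN_WINDOW}, got {window_len_samples}")
    if step_samples is None:
        step_samples = window_len_samples
    if step_samples < 1:
        raise InvalidInputError(f"step_samples must be >= 1, got {step_samples}")
    x = series.samples
    if x.size < window_len_samples:
        raise InvalidInputError(
            f"series of {x.size} samples is shorter than one window ({window_len_samples})"
        )
    n_windows = (x.size - window_len_samples) // step_samples + 1
    rows = []
    for k in range(n_windows):
        lo = k * step_samples
        feats = window_features(x[lo : lo + window_len_samples], params)
        rows.append(
            {
                "fruit_id": series.fruit_id,
                "window_start_s": series.t0 + lo / series.fs,
                "window_end_s": series.t0 + (lo + window_len_samples) / series.fs,
                "stage": series.stage_at_start,
                **feats,
            }
        )
    df = pd.DataFrame(rows)
    values = df[list(FEATURE_NAMES)].to_numpy()
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("non-finite feature value encountered")
    return df


@dataclass(frozen=True)
class CentroidModel:
    """Per-stage centroids in a robustly standardized feature space."""

    feature_names: tuple[str, ...]
    center: np.ndarray  # per-feature global median
    scale: np.ndarray  # per-feature IQR (1.0 where the IQR was 0)
    degenerate_features: tuple[str, ...]  # features whose IQR was 0
    centroids: dict[str, np.ndarray]

    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (values - self.center) / self.scale

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "degenerate_features": list(self.degenerate_features),
            "centroids": {k: v.tolist() for k, v in self.centroids.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text: str) -> "CentroidModel":
        payload = json.loads(text)
        return cls(
            feature_names=tuple(payload["feature_names"]),
            center=np.array(payload["center"], dtype=float),
            scale=np.array(payload["scale"], dtype=float),
            degenerate_features=tuple(payload["degenerate_features"]),
            centroids={k: np.array(v, dtype=float) for k, v in payload["centroids"].items()},
        )

    @classmethod
    def load(cls, path) -> "CentroidModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass(frozen=True)
class ClassificationResult:
    predictions: pd.Series
    confusion: pd.DataFrame | None
    accuracy: float | None


def fit_centroids(table: pd.DataFrame, feature_names=FEATURE_NAMES) -> CentroidModel:
    """Fit per-stage centroids on a labeled feature table.

    Features are standardized by the global per-feature median and IQR
    (features with zero IQR get scale 1 and are flagged); each stage's
    centroid is the mean of its standardized rows. Requires at least two
    stages and two rows per stage.
    """
    feature_names = tuple(feature_names)
    for name in feature_names:
        if name not in table.columns:
            raise InvalidInputError(f"feature table missing column {name!r}")
    if "stage" not in table.columns:
        raise InvalidInputError("feature table has no 'stage' column")
    labeled = table.dropna(subset=["stage"])
    stages = sorted(labeled["stage"].unique(), key=STAGE_ORDER.index)
    if len(stages) < 2:
        raise InvalidInputError(f"need at least 2 stages to fit centroids, got {list(stages)}")
    counts = labeled["stage"].value_counts()
    thin = [s for s in stages if counts[s] < 2]
    if thin:
        raise InvalidInputError(f"stage(s) {thin} have fewer than 2 rows")
    values = labeled[list(feature_names)].to_numpy(dtype=float)
    center = np.median(values, axis=0)
    q75, q25 = np.percentile(values, [75, 25], axis=0)
    iqr = q75 - q25
    degenerate = tuple(np.array(feature_names)[iqr == 0])
    scale = np.where(iqr == 0, 1.0, iqr)
    z = (values - center) / scale
    centroids = {
        stage: z[(labeled["stage"] == stage).to_numpy()].mean(axis=0) for stage in stages
    }
    return CentroidModel(
        feature_names=feature_names,
        center=center,
        scale=scale,
        degenerate_features=degenerate,
        centroids=centroids,
    )


def classify(model: CentroidModel, table: pd.DataFrame) -> ClassificationResult:
    """Assign each row the stage of its nearest centroid.

    Distance is Euclidean in the standardized feature space; ties are
    broken by canonical stage order. When the table carries stage labels a
    confusion matrix (rows true, columns predicted) and accuracy are
    reported.
    """
    for name in model.feature_names:
        if name not in table.columns:
            raise InvalidInputError(f"feature table missing model feature {name!r}")
    stages = sorted(model.centroids, key=STAGE_ORDER.index)
    z = model.standardize(table[list(model.feature_names)].to_numpy(dtype=float))
    cents = np.stack([model.centroids[s] for s in stages])
    d = np.linalg.norm(z[:, None, :] - cents[None, :, :], axis=2)
    pred = pd.Series([stages[i] for i in np.argmin(d, axis=1)], index=table.index, name="predicted_stage")
    confusion = None
    accuracy = None
    if "stage" in table.columns and table["stage"].notna().all():
        truth = table["stage"]
        all_stages = sorted(set(stages) | set(truth.unique()), key=STAGE_ORDER.index)
        confusion = pd.crosstab(truth, pred).reindex(
            index=all_stages, columns=all_stages, fill_value=0
        )
        confusion.index.name = "true"
        confusion.columns.name = "predicted"
        accuracy = float((pred == truth).mean())
    return ClassificationResult(predictions=pred, confusion=confusion, accuracy=accuracy)
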