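"""Five-feature representation of epoch-averaged fNIRS time courses.

For each subject-session the trial-averaged -1..60 s epoch (496 time
samples x 15 channels) is reduced, at every time sample, to five
statistics of the 15-channel spatial vector: mean, variance, slope,
kurtosis and skewness.  Conventions (the source framework states
none): population (divide-by-n) variance, least-squares slope of
value against channel index, Fisher (excess) kurtosis, and skewness /
kurtosis defined as 0 when the spatial variance is exactly 0.

This yields 496 rows x 5 columns per subject-session — 74,400 feature
elements for a 30-subject single-session cohort — and features are
min-max rescaled to [0, 1], with the min/max fit on a designated row
subset (training folds by default) and stored for reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

__all__ = ["FEATURE_NAMES", "FeatureMatrix", "extract_features",
           "spatial_features", "rescale", "apply_scaling",
           "concat_features", "total_elements"]

FEATURE_NAMES = ("mean", "variance", "slope", "kurtosis", "skewness")
ID_COLUMNS = ("subject", "session", "label", "sample")


@dataclass
class FeatureMatrix:
    """Tidy per-time-sample feature table plus the scaling fit on it."""

    table: pd.DataFrame
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.table[list(FEATURE_NAMES)].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.table["session"].to_numpy()

    @property
    def n_elements(self) -> int:
        """Total feature elements (rows x 5)."""
        return len(self.table) * len(FEATURE_NAMES)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def spatial_features(values: np.ndarray) -> np.ndarray:
    """Five statistics of one spatial sample vector (n_channels,).

    Returns (mean, population variance, LS slope vs. channel index,
    excess kurtosis, skewness); the last two are 0 by convention when
    the variance is 0.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 channels for kurtosis/skewness")
    mean = v.mean()
    dev = v - mean
    var = float(np.mean(dev ** 2))
    idx = np.arange(1, n + 1, dtype=float)
    idx_dev = idx - idx.mean()
    slope = float(np.dot(idx_dev, dev) / np.dot(idx_dev, idx_dev))
    if var == 0.0:
        kurt = skew = 0.0
    else:
        m2 = var
        kurt = float(np.mean(dev ** 4) / m2 ** 2 - 3.0)
        skew = float(np.mean(dev ** 3) / m2 ** 1.5)
    return np.array([mean, var, slope, kurt, skew])


def _features_over_channels(avg: np.ndarray) -> np.ndarray:
    """Vectorized spatial_features for every time sample of (time, ch)."""
    n = avg.shape[1]
    mean = avg.mean(axis=1)
    dev = avg - mean[:, None]
    var = np.mean(dev ** 2, axis=1)
    idx = np.arange(1, n + 1, dtype=float)
    idx_dev = idx - idx.mean()
    slope = dev @ idx_dev / np.dot(idx_dev, idx_dev)
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = np.where(var > 0, np.mean(dev ** 4, axis=1) / var ** 2 - 3.0, 0.0)
        skew = np.where(var > 0, np.mean(dev ** 3, axis=1) / var ** 1.5, 0.0)
    return np.column_stack([mean, var, slope, kurt, skew])


def extract_features(e: EpochSet, axis: str = "channels") -> FeatureMatrix:
    """Per-time-sample features of the trial-averaged epoch.

    ``axis="channels"`` (default) computes the five statistics across
    the channel vector at each time sample, one row per sample.  The
    sensitivity-analysis alternative ``axis="time"`` computes them per
    channel over the 0..60 s window instead (one row per channel).
    """
    if e.n_trials < 1:
        raise ValueError("need at least one epoch")
    avg = e.trial_average()
    if axis == "channels":
        feats = _features_over_channels(avg)
        samples = np.arange(avg.shape[0])
    elif axis == "time":
        task = avg[e.task_slice()]
        feats = _features_over_channels(task.T)
        samples = np.arange(task.shape[1])
    else:
        raise ValueError(f"unknown feature axis {axis!r}")
    table = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    table.insert(0, "sample", samples)
    table.insert(0, "label", e.label)
    table.insert(0, "session", e.session)
    table.insert(0, "subject", e.subject_id)
    return FeatureMatrix(table=table)


def rescale(fm: FeatureMatrix, fit_on: np.ndarray | None = None) -> FeatureMatrix:
    """Min-max rescale features to [0, 1].

    ``fit_on`` is a boolean/index row mask naming the partition used to
    estimate the per-feature min and max (all rows when None).  Rows
    outside the fitted partition may land outside [0, 1]; no clipping
    is applied.  Rescaling twice with the same fit set is idempotent.
    """
    table = fm.table.copy()
    fit_rows = table if fit_on is None else table.iloc[np.asarray(fit_on)]
    scaling: dict[str, tuple[float, float]] = {}
    for name in FEATURE_NAMES:
        lo, hi = float(fit_rows[name].min()), float(fit_rows[name].max())
        if hi <= lo:
            raise ValueError(
                f"feature {name!r} is constant on the fit partition; "
                f"remove it before rescaling")
        scaling[name] = (lo, hi)
        table[name] = (table[name] - lo) / (hi - lo)
    return FeatureMatrix(table=table, scaling=scaling)


def apply_scaling(fm: FeatureMatrix,
                  scaling: dict[str, tuple[float, float]]) -> FeatureMatrix:
    """Apply a stored min-max scaling to new data (may exceed [0, 1])."""
    table = fm.table.copy()
    for name in FEATURE_NAMES:
        lo, hi = scaling[name]
        table[name] = (table[name] - lo) / (hi - lo)
    return FeatureMatrix(table=table, scaling=dict(scaling))


def concat_features(fms: list[FeatureMatrix]) -> FeatureMatrix:
    """Pool feature tables (e.g. both sessions of one subject)."""
    return FeatureMatrix(
        table=pd.concat([fm.table for fm in fms], ignore_index=True))


def total_elements(fms: list[FeatureMatrix]) -> int:
    return sum(fm.n_elements for fm in fms)
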