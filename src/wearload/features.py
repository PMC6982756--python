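"""One-second windowing and statistical feature extraction.

Each feature vector summarizes a window of 20 triaxial samples (one second
at 20 Hz) with 15 statistics: per-axis mean, standard deviation, variance
and mean absolute deviation, plus the three pairwise differences of axis
means.  Dispersion statistics use the population convention (divide by n),
which keeps ``var == std**2`` exact for every window.

The optimized feature set drops the four statistics with the lowest Gini
importance in the trained forest — the y-axis mean, the y- and z-axis mean
absolute deviations and the x−y mean difference — leaving 11 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sensor_io import AccelSample, SAMPLES_PER_SECOND, Session

__all__ = [
    "FULL_FEATURES",
    "PRUNED_DROP",
    "PRUNED_FEATURES",
    "FeatureSetSpec",
    "segment_windows",
    "compute_feature_vector",
    "prune_features",
    "featurize_session",
    "featurize_records",
]

#: Canonical feature order: means, standard deviations, variances, mean
#: absolute deviations, then differences of means.
FULL_FEATURES: tuple[str, ...] = (
    "mean_x", "mean_y", "mean_z",
    "std_x", "std_y", "std_z",
    "var_x", "var_y", "var_z",
    "mad_x", "mad_y", "mad_z",
    "dmean_xy", "dmean_yz", "dmean_xz",
)

#: Features removed by importance-based pruning of the full set.
PRUNED_DROP: frozenset[str] = frozenset({"mean_y", "mad_y", "mad_z", "dmean_xy"})

#: The optimized 11-feature set, in canonical order.
PRUNED_FEATURES: tuple[str, ...] = tuple(f for f in FULL_FEATURES if f not in PRUNED_DROP)

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class FeatureSetSpec:
    """An ordered selection of feature names in effect for a model."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @classmethod
    def full(cls) -> "FeatureSetSpec":
        return cls(FULL_FEATURES)

    @classmethod
    def pruned(cls) -> "FeatureSetSpec":
        return cls(PRUNED_FEATURES)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


def _as_array(window: Sequence[AccelSample] | np.ndarray) -> np.ndarray:
    if isinstance(window, np.ndarray):
        arr = np.asarray(window, dtype=float)
    else:
        arr = np.array([(s.ax, s.ay, s.az) for s in window], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"window must be n×3, got shape {arr.shape}")
    return arr


def segment_windows(
    samples: Sequence[AccelSample] | np.ndarray,
    window_len: int = SAMPLES_PER_SECOND,
) -> list:
    """Split a time-ordered sample stream into consecutive non-overlapping
    windows of exactly ``window_len`` samples.

    A trailing incomplete group is discarded, so the number of windows is
    ``floor(n / window_len)``.
    """
    if window_len < 1:
        raise ValueError(f"window_len must be >= 1, got {window_len}")
    n = len(samples)
    n_windows = n // window_len
    return [samples[i * window_len : (i + 1) * window_len] for i in range(n_windows)]


def compute_feature_vector(window: Sequence[AccelSample] | np.ndarray) -> dict[str, float]:
    """Compute the 15 windowed statistics for one 20-sample window.

    Returns a dict keyed by canonical feature name.  Variance and standard
    deviation divide by n (population form); MAD is the mean absolute
    deviation from the axis mean.
    """
    arr = _as_array(window)
    if arr.shape[0] != SAMPLES_PER_SECOND:
        raise ValueError(
            f"window must hold exactly {SAMPLES_PER_SECOND} samples, got {arr.shape[0]}"
        )
    means = arr.mean(axis=0)
    stds = arr.std(axis=0)  # population (ddof=0)
    variances = arr.var(axis=0)
    mads = np.abs(arr - means).mean(axis=0)
    values = np.concatenate(
        [
            means,
            stds,
            variances,
            mads,
            [means[0] - means[1], means[1] - means[2], means[0] - means[2]],
        ]
    )
    return dict(zip(FULL_FEATURES, values.tolist()))


def prune_features(vectors: pd.DataFrame, spec: FeatureSetSpec) -> pd.DataFrame:
    """Project a feature matrix onto the features named in ``spec``.

    The label column, when present, is carried through unchanged; the input
    frame is not modified.  Unknown feature names raise ``ValueError``.
    """
    unknown = [name for name in spec.names if name not in vectors.columns]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    columns = list(spec.names)
    if LABEL_COLUMN in vectors.columns:
        columns.append(LABEL_COLUMN)
    return vectors.loc[:, columns].copy()


def featurize_records(records: Iterable, spec: FeatureSetSpec | None = None) -> pd.DataFrame:
    """One labeled feature vector per second-record, in input order."""
    if spec is None:
        spec = FeatureSetSpec.full()
    rows = []
    labels = []
    for rec in records:
        rows.append(compute_feature_vector(rec.samples))
        labels.append(rec.label)
    df = pd.DataFrame(rows, columns=list(FULL_FEATURES))
    df[LABEL_COLUMN] = labels
    return prune_features(df, spec)


def featurize_session(session: Session, spec: FeatureSetSpec | None = None) -> pd.DataFrame:
    """Feature matrix for a whole session: one row per record, label copied
    from the record, order preserved."""
    return featurize_records(session.records, spec)
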