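"""Voxel clustering and per-cluster statistic profiles.

Voxels are grouped by feature similarity (k-means by default, Ward
agglomerative as an option) on z-scored features; the per-cluster profile is
the 6-statistic-per-feature vector (mean, std, kurtosis, skewness, min, max)
computed on the *raw* feature values.

Conventions: population standard deviation, Fisher moment skewness, excess
kurtosis (normal -> 0). Singleton clusters get std = 0 and skewness =
kurtosis = 0 by convention and are flagged as degenerate.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

from .volume_stack import VoxelTable

__all__ = [
    "ClusterAssignment",
    "ClusterProfile",
    "standardize_features",
    "cluster_voxels",
    "cluster_profiles",
    "profiles_to_frame",
    "STAT_NAMES",
]

STAT_NAMES = ("mean", "std", "kurtosis", "skewness", "min", "max")


@dataclass
class ClusterAssignment:
    """Per-row cluster labels in ``[0, k)``; every label occurs at least once."""

    labels: np.ndarray
    k: int
    method: str
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.k:
            raise ValueError(f"labels outside [0, {self.k})")
        if len(present) != self.k:
            raise ValueError("every label in [0, k) must occur at least once")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class ClusterProfile:
    """6*N statistic vector of one cluster, ordered
    ``(f1_mean, f1_std, f1_kurtosis, f1_skewness, f1_min, f1_max, f2_mean, ...)``."""

    cluster_id: int
    stats: np.ndarray
    size: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.ndim != 1 or self.stats.shape[0] % len(STAT_NAMES):
            raise ValueError("stats must be a flat vector of length 6*n_features")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        by_stat = self.stats.reshape(-1, len(STAT_NAMES))
        mean, std, _, _, mn, mx = by_stat.T
        if (std < -1e-12).any() or (mn > mean + 1e-9).any() or (mean > mx + 1e-9).any():
            raise ValueError(f"cluster {self.cluster_id}: invalid moment ordering")

    @property
    def n_features(self) -> int:
        return self.stats.shape[0] // len(STAT_NAMES)


def stat_vector_names(feature_names: list[str]) -> list[str]:
    return [f"{f}_{s}" for f in feature_names for s in STAT_NAMES]


def standardize_features(table: VoxelTable) -> VoxelTable:
    """Z-score every feature column (population sd) over the masked voxels.

    Zero-variance columns are set to 0 and reported with a warning rather
    than raising: a constant acquisition is degenerate but not fatal.
    """
    if table.n_rows < 2:
        raise ValueError("standardization needs at least 2 rows")
    x = table.features
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    flat = sd == 0
    if flat.any():
        names = [table.feature_names[i] for i in np.nonzero(flat)[0]]
        warnings.warn(
            f"zero-variance feature columns set to 0: {', '.join(names)}",
            stacklevel=2,
        )
    safe_sd = np.where(flat, 1.0, sd)
    z = (x - mu) / safe_sd
    z[:, flat] = 0.0
    return dataclasses.replace(table, features=z)


def cluster_voxels(
    table: VoxelTable,
    k: int,
    seed: int = 0,
    method: str = "kmeans",
    standardize: bool = True,
    n_init: int = 10,
) -> ClusterAssignment:
    """Group the table's rows into ``k`` clusters by feature similarity.

    Deterministic given ``(table, k, seed, method)``. Empty clusters (rare
    with k-means) are compacted and ``k`` reduced with a warning.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2; got {k}")
    if k >= table.n_rows:
        raise ValueError(f"k={k} must be smaller than the row count {table.n_rows}")
    x = standardize_features(table).features if standardize else table.features

    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = model.fit_predict(x)
    elif method == "agglomerative":
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    present = np.unique(labels)
    if len(present) < k:
        warnings.warn(
            f"{k - len(present)} empty clusters compacted; k reduced to {len(present)}",
            stacklevel=2,
        )
        remap = {old: new for new, old in enumerate(present)}
        labels = np.array([remap[v] for v in labels])
        k = len(present)
    return ClusterAssignment(labels=labels, k=k, method=method, seed=seed)


def _moments(values: np.ndarray) -> np.ndarray:
    """Per-feature (mean, std, kurtosis, skewness, min, max) for one cluster,
    flattened feature-major."""
    mean = values.mean(axis=0)
    std = values.std(axis=0)  # population sd
    mn = values.min(axis=0)
    mx = values.max(axis=0)
    if values.shape[0] > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            kurt = stats.kurtosis(values, axis=0, fisher=True, bias=True)
            skew = stats.skew(values, axis=0, bias=True)
        # constant features within the cluster: moments undefined -> 0
        kurt = np.where(std == 0, 0.0, np.nan_to_num(kurt, nan=0.0))
        skew = np.where(std == 0, 0.0, np.nan_to_num(skew, nan=0.0))
    else:
        kurt = np.zeros_like(mean)
        skew = np.zeros_like(mean)
    return np.column_stack([mean, std, kurt, skew, mn, mx]).ravel()


def cluster_profiles(
    table: VoxelTable, assignment: ClusterAssignment
) -> list[ClusterProfile]:
    """One :class:`ClusterProfile` per cluster, computed on raw (unstandardized)
    feature values."""
    if assignment.labels.shape[0] != table.n_rows:
        raise ValueError("assignment does not match table rows")
    profiles = []
    for cid in range(assignment.k):
        rows = table.features[assignment.labels == cid]
        degenerate = rows.shape[0] == 1
        if degenerate:
            warnings.warn(
                f"cluster {cid} is a singleton; std/kurtosis/skewness set to 0",
                stacklevel=2,
            )
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                stats=_moments(rows),
                size=rows.shape[0],
                degenerate=degenerate,
            )
        )
    return profiles


def profiles_to_frame(
    profiles: list[ClusterProfile], feature_names: list[str]
) -> pd.DataFrame:
    """Profiles as a DataFrame (one row per cluster, labeled stat columns)."""
    cols = stat_vector_names(feature_names)
    df = pd.DataFrame(
        [p.stats for p in profiles],
        index=pd.Index([p.cluster_id for p in profiles], name="cluster_id"),
        columns=cols,
    )
    df.insert(0, "size", [p.size for p in profiles])
    return df
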