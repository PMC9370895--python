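"""Associating a subject's motor modules with reference clusters.

Each module is embedded in a 2m-dimensional feature space: its m muscle
weights concatenated with its basic pattern time-interpolated down to m
points, every feature Z-scored by the reference cohort's statistics.
Reference prototypes are k-means centers in this space; a module belongs to
its nearest cluster only if the mean per-feature distance to the center is
at most 0.8 and the maximum per-feature distance at most 2, otherwise it is
left unclassified. Pattern similarity is the Pearson correlation and weight
similarity the normalized scalar product (cosine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.cluster import KMeans

from .errors import ParameterError, UndefinedMetricError
from .synergy import compute_coa

MEAN_DISTANCE_THRESHOLD = 0.8
MAX_DISTANCE_THRESHOLD = 2.0


@dataclass
class FeatureStats:
    """Per-feature Z-scoring statistics of the reference cohort."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray = None  # boolean mask of non-degenerate features

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.kept is None:
            self.kept = self.sd > 0
        else:
            self.kept = np.asarray(self.kept, dtype=bool)


@dataclass
class ReferenceClusters:
    """k-means cluster model of reference modules in the Z-scored space."""

    centers: np.ndarray                   # k x n_kept_features
    stats: FeatureStats
    reference_patterns: np.ndarray        # k x n_phase, mean member pattern
    reference_weights: np.ndarray         # k x m, mean member weights
    mean_threshold: float = MEAN_DISTANCE_THRESHOLD
    max_threshold: float = MAX_DISTANCE_THRESHOLD
    labels: list[int] = field(default_factory=list)  # chronological module ids 1..k

    @property
    def k(self) -> int:
        return self.centers.shape[0]


@dataclass
class ModuleAssignment:
    """Outcome of matching one module against the reference clusters."""

    cluster: int | None            # 1-based module id, None = unclassified
    mean_distance: float
    max_distance: float
    pattern_r: float | None = None
    weight_cosine: float | None = None

    @property
    def assigned(self) -> bool:
        return self.cluster is not None

    def as_dict(self) -> dict:
        return {
            "cluster": self.cluster if self.assigned else "unclassified",
            "mean_distance": float(self.mean_distance),
            "max_distance": float(self.max_distance),
            "pattern_r": None if self.pattern_r is None else float(self.pattern_r),
            "weight_cosine": None
            if self.weight_cosine is None
            else float(self.weight_cosine),
        }


def resample_pattern(pattern: np.ndarray, m: int) -> np.ndarray:
    """Linear time-interpolation of a pattern down to m points."""
    pattern = np.asarray(pattern, dtype=float)
    src = np.linspace(0.0, 1.0, pattern.size)
    dst = np.linspace(0.0, 1.0, m)
    return np.interp(dst, src, pattern)


def raw_feature_vector(weights: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """[m weights, pattern resampled to m] before Z-scoring; length 2m."""
    weights = np.asarray(weights, dtype=float)
    return np.concatenate([weights, resample_pattern(pattern, weights.size)])


def build_feature_vector(
    weights: np.ndarray, pattern: np.ndarray, stats: FeatureStats
) -> np.ndarray:
    """Z-scored 2m feature vector; degenerate (sd = 0) features are dropped."""
    raw = raw_feature_vector(weights, pattern)
    if raw.size != stats.mean.size:
        raise ParameterError(
            f"feature length {raw.size} != reference statistics length {stats.mean.size}"
        )
    z = (raw[stats.kept] - stats.mean[stats.kept]) / stats.sd[stats.kept]
    return z


def fit_reference_clusters(
    weights: np.ndarray,
    patterns: np.ndarray,
    k: int,
    seed: int = 0,
    *,
    mean_threshold: float = MEAN_DISTANCE_THRESHOLD,
    max_threshold: float = MAX_DISTANCE_THRESHOLD,
) -> ReferenceClusters:
    """Cluster a cohort's modules with k-means (20 seeded restarts).

    ``weights`` is (n_modules, m) and ``patterns`` (n_modules, n_phase).
    Clusters are relabeled 1..k in chronological order of the center of
    activity of their mean member pattern, so "module 1" is the earliest
    burst in the gait cycle.
    """
    weights = np.asarray(weights, dtype=float)
    patterns = np.asarray(patterns, dtype=float)
    n_modules = weights.shape[0]
    if k < 1 or k > n_modules:
        raise ParameterError(f"k={k} outside 1..{n_modules}")
    raw = np.stack([raw_feature_vector(w, p) for w, p in zip(weights, patterns)])
    stats = FeatureStats(raw.mean(axis=0), raw.std(axis=0, ddof=0))
    z = (raw[:, stats.kept] - stats.mean[stats.kept]) / stats.sd[stats.kept]
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    member = km.fit_predict(z)

    # chronological relabeling by CoA of each cluster's mean pattern
    coas = []
    ref_patterns = np.empty((k, patterns.shape[1]))
    ref_weights = np.empty((k, weights.shape[1]))
    for c in range(k):
        mask = member == c
        mean_pattern = patterns[mask].mean(axis=0) if mask.any() else patterns.mean(axis=0)
        ref_patterns[c] = mean_pattern
        ref_weights[c] = weights[mask].mean(axis=0) if mask.any() else weights.mean(axis=0)
        coa, defined = compute_coa(np.clip(mean_pattern, 0, None))
        coas.append(coa if defined else np.inf)
    order = np.argsort(coas, kind="stable")
    return ReferenceClusters(
        centers=km.cluster_centers_[order],
        stats=stats,
        reference_patterns=ref_patterns[order],
        reference_weights=ref_weights[order],
        mean_threshold=mean_threshold,
        max_threshold=max_threshold,
        labels=list(range(1, k + 1)),
    )


def assign_module(
    vector: np.ndarray,
    clusters: ReferenceClusters,
    pattern: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> ModuleAssignment:
    """Match one Z-scored feature vector against the cluster centers.

    The nearest center by mean per-feature distance is selected; the module
    is assigned to it only when the mean per-feature distance does not
    exceed ``mean_threshold`` and the maximum per-feature distance does not
    exceed ``max_threshold``. Similarities to the winning cluster's
    reference pattern/weights are attached when those inputs are given.
    """
    vector = np.asarray(vector, dtype=float)
    dev = np.abs(clusters.centers - vector[None, :])
    mean_d = dev.mean(axis=1)
    max_d = dev.max(axis=1)
    best = int(np.argmin(mean_d))
    ok = mean_d[best] <= clusters.mean_threshold and max_d[best] <= clusters.max_threshold
    assignment = ModuleAssignment(
        cluster=clusters.labels[best] if ok else None,
        mean_distance=float(mean_d[best]),
        max_distance=float(max_d[best]),
    )
    if pattern is not None:
        assignment.pattern_r = pattern_similarity(
            pattern, clusters.reference_patterns[best]
        )
    if weights is not None:
        assignment.weight_cosine = weight_similarity(
            weights, clusters.reference_weights[best]
        )
    return assignment


def pattern_similarity(p1: np.ndarray, p2: np.ndarray) -> float:
    """Pearson correlation between two equal-length patterns."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ParameterError("patterns must have equal length")
    if np.ptp(p1) == 0 or np.ptp(p2) == 0:
        raise UndefinedMetricError("pattern similarity undefined for constant input")
    return float(np.corrcoef(p1, p2)[0, 1])


def weight_similarity(w1: np.ndarray, w2: np.ndarray) -> float:
    """Normalized scalar product (cosine) between two weight vectors."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ParameterError("weight vectors must have equal length")
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0:
        raise UndefinedMetricError("weight similarity undefined for a zero vector")
    return float(np.dot(w1, w2) / (n1 * n2))


def save_clusters(clusters: ReferenceClusters, path: str | Path) -> None:
    data = {
        "schema": "pepato-clusters-1",
        "centers": clusters.centers.tolist(),
        "feature_mean": clusters.stats.mean.tolist(),
        "feature_sd": clusters.stats.sd.tolist(),
        "feature_kept": [bool(b) for b in clusters.stats.kept],
        "reference_patterns": clusters.reference_patterns.tolist(),
        "reference_weights": clusters.reference_weights.tolist(),
        "mean_threshold": float(clusters.mean_threshold),
        "max_threshold": float(clusters.max_threshold),
        "labels": list(clusters.labels),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_clusters(path: str | Path) -> ReferenceClusters:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    stats = FeatureStats(
        np.asarray(d["feature_mean"]),
        np.asarray(d["feature_sd"]),
        np.asarray(d["feature_kept"], dtype=bool),
    )
    return ReferenceClusters(
        centers=np.asarray(d["centers"], dtype=float),
        stats=stats,
        reference_patterns=np.asarray(d["reference_patterns"], dtype=float),
        reference_weights=np.asarray(d["reference_weights"], dtype=float),
        mean_threshold=float(d["mean_threshold"]),
        max_threshold=float(d["max_threshold"]),
        labels=[int(x) for x in d["labels"]],
    )
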