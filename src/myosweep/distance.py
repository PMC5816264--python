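"""Inter-class separability in feature space.

The pairwise statistic is the half-quadratic Mahalanobis-type index

    d(i, j) = 1/2 (mu_i - mu_j)^T [ (Sigma_i + Sigma_j) / 2 ]^{-1} (mu_i - mu_j)

(optionally its square root), and the D_out summary is the mean over classes
of each class's minimum pairwise distance to any other class — a small D_out
means at least one confusable neighbour per class. Sample covariances in 48
dimensions estimated from as few as 5 samples are singular, so a ridge
(scaled identity) is added before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .features import feature_columns
from .sweep import build_training_set


@dataclass
class ClassStats:
    gesture: str
    centroid: np.ndarray
    covariance: np.ndarray
    n: int

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (self.centroid.size, self.centroid.size):
            raise ValueError("covariance shape must match centroid dimension")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if self.n < 2:
            raise ValueError("need at least 2 samples per class")


@dataclass
class DistanceReport:
    pairwise: pd.DataFrame
    d_out: float
    assignment_label: str


def default_ridge(features: pd.DataFrame, rel: float = 1e-3) -> float:
    """Ridge = ``rel`` x mean diagonal of the pooled sample covariance."""
    cols = feature_columns(features)
    X = features[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate a ridge")
    pooled = np.cov(X, rowvar=False, ddof=1)
    pooled = np.atleast_2d(pooled)
    return float(rel * np.mean(np.diag(pooled)))


def class_stats(features: pd.DataFrame, gesture: str,
                ridge: float = 0.0) -> ClassStats:
    """Sample mean and ridged sample covariance of one gesture's features."""
    cols = feature_columns(features)
    rows = features.loc[features["gesture"] == gesture, cols]
    if rows.shape[0] == 0:
        raise ValueError(f"unknown gesture '{gesture}'")
    if rows.shape[0] < 2:
        raise ValueError(f"gesture '{gesture}' has fewer than 2 samples")
    X = rows.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    cov = cov + ridge * np.eye(cov.shape[0])
    return ClassStats(gesture=gesture, centroid=mu, covariance=cov,
                      n=X.shape[0])


def pair_distance(a: ClassStats, b: ClassStats, sqrt: bool = False) -> float:
    """Half-quadratic separability index between two class distributions."""
    if a.centroid.size != b.centroid.size:
        raise ValueError("dimension mismatch between class statistics")
    delta = a.centroid - b.centroid
    pooled = 0.5 * (a.covariance + b.covariance)
    val = 0.5 * float(delta @ np.linalg.solve(pooled, delta))
    val = max(val, 0.0)
    return float(np.sqrt(val)) if sqrt else val


def pairwise_matrix(stats: list[ClassStats], sqrt: bool = False) -> pd.DataFrame:
    names = [s.gesture for s in stats]
    m = np.zeros((len(stats), len(stats)))
    for i in range(len(stats)):
        for j in range(i + 1, len(stats)):
            m[i, j] = m[j, i] = pair_distance(stats[i], stats[j], sqrt=sqrt)
    return pd.DataFrame(m, index=names, columns=names)


def d_out(stats: list[ClassStats], sqrt: bool = False) -> float:
    """Mean over classes of the minimum pairwise distance to another class."""
    if len(stats) < 2:
        raise ValueError("D_out needs at least 2 classes")
    mat = pairwise_matrix(stats, sqrt=sqrt).to_numpy()
    mins = []
    for i in range(len(stats)):
        others = np.delete(mat[i], i)
        mins.append(others.min())
    return float(np.mean(mins))


def distance_report(features: pd.DataFrame, gestures: list[str],
                    ridge: float, label: str,
                    sqrt: bool = False) -> DistanceReport:
    stats = [class_stats(features, g, ridge=ridge) for g in gestures]
    return DistanceReport(pairwise=pairwise_matrix(stats, sqrt=sqrt),
                          d_out=d_out(stats, sqrt=sqrt),
                          assignment_label=label)


@dataclass
class AssignmentComparison:
    """Paired distance reports for two training-set assignments."""

    gestures: tuple[str, ...]
    label_a: str
    label_b: str
    pair_deltas: pd.DataFrame          # per repeat x pair, (b - a)
    d_out_a: np.ndarray
    d_out_b: np.ndarray
    repeats: int

    @property
    def d_out_delta(self) -> np.ndarray:
        return self.d_out_b - self.d_out_a

    def summary(self) -> pd.DataFrame:
        """Mean ± SD of each paired delta plus a paired t test."""
        rows = []
        series = {f"{i}|{j}": self.pair_deltas[f"{i}|{j}"].to_numpy()
                  for i, j in self._pairs()}
        series["d_out"] = self.d_out_delta
        for name, d in series.items():
            t, p = (np.nan, np.nan)
            if self.repeats > 1 and np.std(d) > 0:
                t, p = sstats.ttest_1samp(d, 0.0)
            rows.append({"quantity": name, "delta_mean": float(np.mean(d)),
                         "delta_sd": float(np.std(d)),
                         "t_stat": float(t), "p_value": float(p)})
        return pd.DataFrame(rows)

    def _pairs(self):
        g = self.gestures
        return [(g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g))]


def compare_assignments(
    pool: pd.DataFrame,
    gestures: list[str],
    counts_a: dict[str, int],
    counts_b: dict[str, int],
    repeats: int = 10,
    seed: int = 0,
    ridge: float | None = None,
    sqrt: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> AssignmentComparison:
    """Paired comparison of class separability under two assignments.

    For each repeat, both training sets are drawn from the same candidate
    pool (independent seeded draws), class statistics are estimated on each,
    and the pairwise distances and D_out are compared pairwise across
    repeats (deltas are ``b - a``).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if ridge is None:
        ridge = default_ridge(pool)
    gestures = list(gestures)
    pairs = [(gestures[i], gestures[j])
             for i in range(len(gestures)) for j in range(i + 1, len(gestures))]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(repeats)
    pair_rows, douts_a, douts_b = [], [], []
    for r in range(repeats):
        # both assignments draw from the same per-repeat stream so that the
        # comparison is paired (identical assignments give identical sets)
        set_a = build_training_set(pool, counts_a,
                                   np.random.default_rng(children[r]))
        set_b = build_training_set(pool, counts_b,
                                   np.random.default_rng(children[r]))
        stats_a = [class_stats(set_a, g, ridge=ridge) for g in gestures]
        stats_b = [class_stats(set_b, g, ridge=ridge) for g in gestures]
        mat_a = pairwise_matrix(stats_a, sqrt=sqrt)
        mat_b = pairwise_matrix(stats_b, sqrt=sqrt)
        row = {}
        for i, j in pairs:
            row[f"{i}|{j}"] = float(mat_b.loc[i, j] - mat_a.loc[i, j])
        pair_rows.append(row)
        douts_a.append(d_out(stats_a, sqrt=sqrt))
        douts_b.append(d_out(stats_b, sqrt=sqrt))
    return AssignmentComparison(
        gestures=tuple(gestures), label_a=label_a, label_b=label_b,
        pair_deltas=pd.DataFrame(pair_rows),
        d_out_a=np.asarray(douts_a), d_out_b=np.asarray(douts_b),
        repeats=repeats)
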