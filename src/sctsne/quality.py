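"""Embedding quality metrics at three spatial scales.

KNN (micro): mean fraction of each point's k nearest high-dimensional
neighbours preserved among its k nearest embedding neighbours.  KNC (meso):
the same for class means, averaged over classes.  CPD (macro): Spearman
correlation between high-dimensional and embedded pairwise distances over a
random subsample of points.  The "high-dimensional" matrix is whatever
representation was handed to the embedder (the 50-PC space in the standard
pipeline).  All three are invariant to rigid transforms and uniform scaling
of either space.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

__all__ = ["QualityReport", "knn_preservation", "knc_preservation", "cpd", "evaluate"]


@dataclass
class QualityReport:
    """The three metrics with the parameters they were evaluated at."""

    knn: float
    knn_k: int
    knc: float
    knc_k: int
    cpd: float
    cpd_sample: int
    cpd_seed: int
    cpd_n_pairs: int

    def to_dict(self) -> dict:
        return asdict(self)


def _knn_indices(X: np.ndarray, k: int, chunk: int = 1024) -> np.ndarray:
    """Exact k nearest neighbours per row, self excluded.

    Distance ties are broken by ascending point index: candidates are ordered
    by (distance, index), which makes the result fully deterministic.
    """
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    sq = (X**2).sum(axis=1)
    kk = min(n - 1, k + 8)  # margin so boundary ties can be index-ordered
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (X[start:stop] @ X.T)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        cand = np.argpartition(d2, kk - 1, axis=1)[:, :kk]
        cand = np.sort(cand, axis=1)  # index order first ...
        cd = np.take_along_axis(d2, cand, axis=1)
        order = np.argsort(cd, axis=1, kind="stable")  # ... then stable by distance
        out[start:stop] = np.take_along_axis(cand, order, axis=1)[:, :k]
    return out


def knn_preservation(X: np.ndarray, Y: np.ndarray, k: int = 10) -> float:
    """Mean fraction of k-nearest neighbours shared between X and Y."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    nx = _knn_indices(X, k)
    ny = _knn_indices(Y, k)
    n = X.shape[0]
    shared = np.empty(n)
    for i in range(n):
        shared[i] = np.intersect1d(nx[i], ny[i], assume_unique=True).size
    return float(shared.mean() / k)


def _class_means(M: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    means = np.empty((uniq.size, M.shape[1]))
    for r, lab in enumerate(uniq):
        rows = labels == lab
        if not rows.any():
            raise ValueError(f"class {lab!r} has no members")
        means[r] = M[rows].mean(axis=0)
    return means, uniq


def knc_preservation(
    X: np.ndarray, Y: np.ndarray, labels: np.ndarray, k: int = 10
) -> float:
    """Fraction of k-nearest class means preserved, averaged over classes."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    mx, uniq = _class_means(X, labels)
    my, _ = _class_means(Y, labels)
    if k >= uniq.size:
        raise ValueError(f"k={k} must be < number of classes = {uniq.size}")
    nx = _knn_indices(mx, k)
    ny = _knn_indices(my, k)
    shared = [
        np.intersect1d(nx[i], ny[i], assume_unique=True).size for i in range(uniq.size)
    ]
    return float(np.mean(shared) / k)


def cpd(
    X: np.ndarray, Y: np.ndarray, n_sample: int = 1000, seed: int = 42
) -> float:
    """Spearman correlation of pairwise distances over a random subsample.

    ``n_sample`` points are drawn without replacement (all points when
    n <= n_sample); the correlation runs over all n_sample*(n_sample-1)/2
    pairs with average-rank tie handling.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n > n_sample:
        idx = np.random.default_rng(seed).choice(n, size=n_sample, replace=False)
        X, Y = X[idx], Y[idx]
    dx = pdist(X)
    dy = pdist(Y)
    rho = spearmanr(dx, dy).statistic
    return float(rho)


def evaluate(
    X: np.ndarray,
    Y: np.ndarray,
    labels: np.ndarray | None = None,
    knn_k: int = 10,
    knc_k: int = 10,
    cpd_sample: int = 1000,
    seed: int = 42,
) -> QualityReport:
    """Compute all three metrics; KNC is NaN when no labels are given."""
    m = min(cpd_sample, X.shape[0])
    return QualityReport(
        knn=knn_preservation(X, Y, k=knn_k),
        knn_k=knn_k,
        knc=(
            knc_preservation(X, Y, labels, k=knc_k) if labels is not None else float("nan")
        ),
        knc_k=knc_k,
        cpd=cpd(X, Y, n_sample=cpd_sample, seed=seed),
        cpd_sample=m,
        cpd_seed=seed,
        cpd_n_pairs=m * (m - 1) // 2,
    )
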