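"""High-dimensional similarities: perplexity-calibrated Gaussian kernels.

Each point i gets a conditional distribution p_{j|i} over its neighbours,
Gaussian in squared Euclidean distance with a per-point bandwidth sigma_i
chosen by bisection so that the distribution's perplexity (exponentiated
base-2 entropy) hits a target.  Only the 3*perplexity nearest neighbours of
each point carry mass; the rest are exactly zero.  Multi-scale similarities
average the conditional distributions calibrated at several perplexities
(typically 30 and n/100).  Symmetrisation p_ij = (p_{i|j} + p_{j|i}) / (2n)
yields the joint distribution the embedding optimiser matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from numba import njit
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ConditionalAffinities",
    "AffinityMatrix",
    "calibrate_row",
    "conditional_affinities",
    "multiscale_conditional",
    "symmetrize",
    "affinities_for",
]

_SIGMA2_LO = 1e-20
_SIGMA2_HI = 1e20


@dataclass
class ConditionalAffinities:
    """Row-stochastic sparse conditional distributions p_{j|i}.

    ``rows`` is an n x n CSR matrix whose i-th row sums to 1 with at most
    3*max(perplexity) nonzeros and a zero diagonal.  ``sigmas`` has one row of
    per-point bandwidths per calibrated perplexity.
    """

    rows: sp.csr_matrix
    sigmas: np.ndarray  # (n_scales, n)
    perplexity_targets: tuple[float, ...]

    @property
    def n(self) -> int:
        return self.rows.shape[0]


@dataclass
class AffinityMatrix:
    """Symmetric joint similarities p_ij, nonnegative, summing to 1."""

    P: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.P.shape[0]


@njit(cache=True)
def _calibrate_kernel(D2, target, tol, max_iter):  # pragma: no cover - numba
    n, k = D2.shape
    P = np.empty((n, k))
    sigmas = np.empty(n)
    fail = -1
    log_lo0 = np.log(_SIGMA2_LO)
    log_hi0 = np.log(_SIGMA2_HI)
    for i in range(n):
        lo = log_lo0
        hi = log_hi0
        ok = False
        s2 = 1.0
        p = np.empty(k)
        for _ in range(max_iter):
            ls = 0.5 * (lo + hi)
            s2 = np.exp(ls)
            mn = D2[i, 0]
            for j in range(1, k):
                if D2[i, j] < mn:
                    mn = D2[i, j]
            Z = 0.0
            for j in range(k):
                p[j] = np.exp(-(D2[i, j] - mn) / (2.0 * s2))
                Z += p[j]
            H = 0.0
            for j in range(k):
                p[j] /= Z
                if p[j] > 0.0:
                    H -= p[j] * np.log2(p[j])
            perp = 2.0**H
            if abs(perp - target) <= tol:
                ok = True
                break
            if perp > target:
                hi = ls
            else:
                lo = ls
        for j in range(k):
            P[i, j] = p[j]
        sigmas[i] = np.sqrt(s2)
        if not ok and fail < 0:
            fail = i
    return P, sigmas, fail


def calibrate_row(
    squared_distances: np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[np.ndarray, float]:
    """Calibrate one Gaussian kernel row to a target perplexity.

    ``squared_distances`` are the squared distances from a point to its
    candidate neighbours (self excluded).  Returns the probability vector over
    those candidates and the bandwidth sigma found by bisection on log sigma^2.

    Raises
    ------
    ValueError
        If the target exceeds the number of candidates (the uniform limit), or
        bisection cannot reach it within ``tol`` (degenerate distances, e.g.
        all equal with a smaller target).
    """
    d2 = np.asarray(squared_distances, dtype=float).reshape(1, -1)
    k = d2.shape[1]
    if k == 0:
        raise ValueError("no candidate neighbours")
    if perplexity > k + tol:
        raise ValueError(
            f"target perplexity {perplexity} unreachable with {k} candidates "
            f"(uniform limit is {k})"
        )
    P, sigmas, fail = _calibrate_kernel(d2, float(perplexity), float(tol), int(max_iter))
    if fail >= 0:
        raise ValueError(
            f"perplexity {perplexity} not reachable within tol={tol} on this row "
            f"(degenerate distances: min={d2.min():.4g}, max={d2.max():.4g}, k={k})"
        )
    return P[0], float(sigmas[0])


def _exact_knn(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(X)
    dist, idx = nn.kneighbors(X)
    # drop the self column (distance 0, guaranteed first among ties of 0 only
    # if indices tie-break; remove wherever it sits per row)
    n = X.shape[0]
    out_idx = np.empty((n, k), dtype=np.int64)
    out_d = np.empty((n, k))
    for i in range(n):
        cols = idx[i] != i
        if cols.sum() == k + 1:  # self not returned (duplicate points); drop last
            cols[-1] = False
        out_idx[i] = idx[i][cols][:k]
        out_d[i] = dist[i][cols][:k]
    return out_d**2, out_idx


def _knn_graph(
    X: np.ndarray,
    k: int,
    knn: Callable[[np.ndarray, int], tuple[np.ndarray, np.ndarray]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(squared distances, indices), each (n, k), self excluded.

    ``knn`` may be a drop-in approximate backend with the same signature and
    return convention; exact brute-force search is the default and the oracle.
    """
    if knn is None:
        return _exact_knn(X, k)
    return knn(X, k)


def _calibrated_rows(
    D2: np.ndarray, perplexity: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    k = D2.shape[1]
    if perplexity > k + tol:
        raise ValueError(
            f"target perplexity {perplexity} exceeds neighbour count {k}; "
            "increase k or lower the perplexity"
        )
    P, sigmas, fail = _calibrate_kernel(D2, float(perplexity), float(tol), int(max_iter))
    if fail >= 0:
        raise ValueError(
            f"row {fail} could not be calibrated to perplexity {perplexity} "
            f"within tol={tol} (degenerate distance profile)"
        )
    return P, sigmas


def multiscale_conditional(
    X: np.ndarray,
    perplexities: Sequence[float],
    tol: float = 1e-5,
    max_iter: int = 200,
    knn: Callable | None = None,
) -> ConditionalAffinities:
    """Average conditional distributions calibrated at several perplexities.

    All scales share the same 3*max(perplexity) nearest-neighbour support so
    the averaged rows remain sparse and still sum to 1.
    """
    if len(perplexities) == 0:
        raise ValueError("need at least one perplexity")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    pmax = max(perplexities)
    if 3 * pmax >= n:
        raise ValueError(f"3*perplexity = {3 * pmax:g} must be < n = {n}")
    k = min(n - 1, int(np.ceil(3 * pmax)))
    D2, idx = _knn_graph(X, k, knn)
    k = D2.shape[1]  # a pluggable backend may return a wider support
    avg = np.zeros_like(D2)
    sigmas = np.empty((len(perplexities), n))
    for s, perp in enumerate(perplexities):
        P, sig = _calibrated_rows(D2, float(perp), tol, max_iter)
        avg += P
        sigmas[s] = sig
    avg /= len(perplexities)
    indptr = np.arange(0, n * k + 1, k)
    rows = sp.csr_matrix((avg.ravel(), idx.ravel(), indptr), shape=(n, n))
    return ConditionalAffinities(
        rows=rows, sigmas=sigmas, perplexity_targets=tuple(float(p) for p in perplexities)
    )


def conditional_affinities(
    X: np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 200,
    knn: Callable | None = None,
) -> ConditionalAffinities:
    """Single-perplexity conditional affinities on 3*perplexity neighbours."""
    return multiscale_conditional(X, [perplexity], tol=tol, max_iter=max_iter, knn=knn)


def symmetrize(cond: ConditionalAffinities) -> AffinityMatrix:
    """Joint similarities p_ij = (p_{i|j} + p_{j|i}) / (2n); sum_ij p_ij = 1."""
    C = cond.rows
    n = C.shape[0]
    P = (C + C.T) / (2.0 * n)
    P = sp.csr_matrix(P)
    P.sort_indices()
    return AffinityMatrix(P=P)


def affinities_for(
    X: np.ndarray,
    perplexities: Sequence[float],
    tol: float = 1e-5,
    knn: Callable | None = None,
) -> AffinityMatrix:
    """Convenience: multi-scale conditional calibration + symmetrisation."""
    return symmetrize(multiscale_conditional(X, perplexities, tol=tol, knn=knn))
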