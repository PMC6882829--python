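"""t-SNE objective, gradient and optimiser.

The embedding Y (n x 2) is fit by minimising the Kullback-Leibler divergence
between the high-dimensional joint similarities p_ij and the Cauchy-kernel
low-dimensional similarities q_ij = w_ij / Z, w_ij = 1 / (1 + ||y_i - y_j||^2).
The gradient splits into an attractive term over the sparse p_ij support and a
dense repulsive term, computed exactly for small n and with a Barnes-Hut
quadtree above that.

Conventions follow the original adaptive-gradient-descent-with-momentum
scheme: gains per coordinate (+0.2 on sign disagreement, x0.8 on agreement,
floored at 0.01), momentum 0.5 switching to 0.8 at iteration 250, early
exaggeration alpha = 12 for the first 250 of 1000 iterations, and *no* factor
4 in the gradient — so a learning rate of n/12 here means the same thing it
means in the Barnes-Hut/FIt-SNE lineage of implementations (scikit-learn
keeps the factor 4; its equivalent rate would be n/48).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import scipy.sparse as sp
from numba import njit

from .affinity import AffinityMatrix
from .preprocess import PCSpace

__all__ = [
    "Embedding",
    "OptimizerConfig",
    "kl_loss",
    "gradient",
    "random_init",
    "pca_init",
    "learning_rate_rule",
    "optimize",
    "repulsion_approx",
    "rotate_embedding",
]

logger = logging.getLogger("sctsne")

#: An embedding is a plain (n, 2) float array of coordinates y_i.
Embedding = np.ndarray

_EXACT_MAX_N = 5000  # dense-gradient reference path below this size
_MAXDEPTH = 48


@dataclass
class OptimizerConfig:
    """Optimisation schedule for :func:`optimize`.

    ``eta`` is the learning rate (use :func:`learning_rate_rule` for the
    max(200, n/12) rule); ``exaggeration`` is the attraction multiplier kept
    *after* the early-exaggeration phase (1 = plain t-SNE, ~4 recommended for
    very large data sets).
    """

    n_iter: int = 1000
    eta: float = 200.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch_iter: int = 250
    early_exaggeration: float = 12.0
    early_exaggeration_iter: int = 250
    exaggeration: float = 1.0
    seed: int = 42
    theta: float = 0.5
    method: Literal["auto", "exact", "bh"] = "auto"

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("learning rate eta must be positive")
        if self.early_exaggeration < 1 or self.exaggeration < 1:
            raise ValueError("exaggeration coefficients must be >= 1")
        if self.n_iter < 0 or self.early_exaggeration_iter < 0:
            raise ValueError("iteration counts must be nonnegative")
        if self.early_exaggeration_iter > self.n_iter and self.n_iter > 0:
            raise ValueError("early_exaggeration_iter must not exceed n_iter")


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _attr_forces(indptr, indices, data, Y):  # pragma: no cover - numba
    n = Y.shape[0]
    F = np.zeros((n, 2))
    for i in range(n):
        xi = Y[i, 0]
        yi = Y[i, 1]
        fx = 0.0
        fy = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            dx = xi - Y[j, 0]
            dy = yi - Y[j, 1]
            pw = data[ptr] / (1.0 + dx * dx + dy * dy)
            fx += pw * dx
            fy += pw * dy
        F[i, 0] = fx
        F[i, 1] = fy
    return F


@njit(cache=True)
def _rep_exact(Y):  # pragma: no cover - numba
    n = Y.shape[0]
    F = np.zeros((n, 2))
    Z = 0.0
    for i in range(n):
        xi = Y[i, 0]
        yi = Y[i, 1]
        fx = 0.0
        fy = 0.0
        for j in range(n):
            if j == i:
                continue
            dx = xi - Y[j, 0]
            dy = yi - Y[j, 1]
            w = 1.0 / (1.0 + dx * dx + dy * dy)
            Z += w
            w2 = w * w
            fx += w2 * dx
            fy += w2 * dy
        F[i, 0] = fx
        F[i, 1] = fy
    return F, Z


@njit(cache=True)
def _rep_barnes_hut(Y, theta):  # pragma: no cover - numba
    n = Y.shape[0]
    minx = Y[0, 0]
    maxx = Y[0, 0]
    miny = Y[0, 1]
    maxy = Y[0, 1]
    for i in range(1, n):
        if Y[i, 0] < minx:
            minx = Y[i, 0]
        if Y[i, 0] > maxx:
            maxx = Y[i, 0]
        if Y[i, 1] < miny:
            miny = Y[i, 1]
        if Y[i, 1] > maxy:
            maxy = Y[i, 1]
    hw0 = 0.5 * max(maxx - minx, maxy - miny) + 1e-12

    cap = 16 * n + 8192
    first_child = np.full(cap, -1, np.int64)
    point_of = np.full(cap, -1, np.int64)
    mass = np.zeros(cap)
    comx = np.zeros(cap)
    comy = np.zeros(cap)
    ncx = np.zeros(cap)
    ncy = np.zeros(cap)
    nhw = np.zeros(cap)
    ncx[0] = 0.5 * (minx + maxx)
    ncy[0] = 0.5 * (miny + maxy)
    nhw[0] = hw0
    n_nodes = 1

    for i in range(n):
        x = Y[i, 0]
        y = Y[i, 1]
        node = 0
        depth = 0
        while True:
            mass[node] += 1.0
            comx[node] += x
            comy[node] += y
            if first_child[node] >= 0:
                q = 0
                if x > ncx[node]:
                    q += 1
                if y > ncy[node]:
                    q += 2
                node = first_child[node] + q
                depth += 1
                continue
            if mass[node] == 1.0:
                point_of[node] = i
                break
            if depth >= _MAXDEPTH:
                break  # bucket of near-duplicate points
            if n_nodes + 4 > cap:
                raise RuntimeError("Barnes-Hut quadtree capacity exceeded")
            j = point_of[node]
            point_of[node] = -1
            fc = n_nodes
            n_nodes += 4
            first_child[node] = fc
            h = 0.5 * nhw[node]
            for q in range(4):
                c = fc + q
                ncx[c] = ncx[node] + (h if (q & 1) else -h)
                ncy[c] = ncy[node] + (h if (q & 2) else -h)
                nhw[c] = h
            xj = Y[j, 0]
            yj = Y[j, 1]
            qj = 0
            if xj > ncx[node]:
                qj += 1
            if yj > ncy[node]:
                qj += 2
            cj = fc + qj
            mass[cj] = 1.0
            comx[cj] = xj
            comy[cj] = yj
            point_of[cj] = j
            q = 0
            if x > ncx[node]:
                q += 1
            if y > ncy[node]:
                q += 2
            node = fc + q
            depth += 1

    F = np.zeros((n, 2))
    Zsum = 0.0
    theta2 = theta * theta
    stack = np.empty(4 * _MAXDEPTH + 64, np.int64)
    for i in range(n):
        xi = Y[i, 0]
        yi = Y[i, 1]
        Zi = -1.0  # cancels the self term w(0) = 1
        fx = 0.0
        fy = 0.0
        top = 0
        stack[top] = 0
        top += 1
        while top > 0:
            top -= 1
            node = stack[top]
            m = mass[node]
            if m == 0.0:
                continue
            dx = xi - comx[node] / m
            dy = yi - comy[node] / m
            d2 = dx * dx + dy * dy
            size = 2.0 * nhw[node]
            if first_child[node] < 0 or size * size < theta2 * d2:
                w = 1.0 / (1.0 + d2)
                Zi += m * w
                mw2 = m * w * w
                fx += mw2 * dx
                fy += mw2 * dy
            else:
                fc = first_child[node]
                stack[top] = fc
                stack[top + 1] = fc + 1
                stack[top + 2] = fc + 2
                stack[top + 3] = fc + 3
                top += 4
        F[i, 0] = fx
        F[i, 1] = fy
        Zsum += Zi
    return F, Zsum


# ---------------------------------------------------------------------------
# objective and gradient
# ---------------------------------------------------------------------------


def _as_P(P: AffinityMatrix | sp.spmatrix) -> sp.csr_matrix:
    M = P.P if isinstance(P, AffinityMatrix) else P
    return sp.csr_matrix(M)


def kl_loss(P: AffinityMatrix | sp.spmatrix, Y: Embedding) -> float:
    """KL divergence sum_{p_ij > 0} p_ij log(p_ij / q_ij); dense in n."""
    Pc = _as_P(P).tocoo()
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if Pc.shape[0] != n:
        raise ValueError(f"P is {Pc.shape[0]}x{Pc.shape[0]} but Y has {n} rows")
    d2 = _pairwise_sq(Y)
    W = 1.0 / (1.0 + d2)
    np.fill_diagonal(W, 0.0)
    Z = W.sum()
    p = Pc.data
    q = W[Pc.row, Pc.col] / Z
    pos = p > 0
    return float(np.sum(p[pos] * np.log(p[pos] / q[pos])))


def _pairwise_sq(Y: np.ndarray) -> np.ndarray:
    s = (Y**2).sum(axis=1)
    d2 = s[:, None] + s[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def gradient(
    P: AffinityMatrix | sp.spmatrix, Y: Embedding, alpha: float = 1.0
) -> np.ndarray:
    """Exact gradient of alpha * attraction + repulsion at Y.

    grad_i = alpha * sum_j p_ij w_ij (y_i - y_j)
             - (1/Z) sum_{j != i} w_ij^2 (y_i - y_j),
    the gradient of the exaggerated KL loss (no factor 4; see module notes).
    Rows sum to zero by translation invariance.
    """
    if alpha < 1:
        raise ValueError("exaggeration alpha must be >= 1")
    Pc = _as_P(P)
    Y = np.ascontiguousarray(Y, dtype=float)
    Fa = _attr_forces(Pc.indptr, Pc.indices, Pc.data, Y)
    Fr, Z = _rep_exact(Y)
    return alpha * Fa - Fr / Z


def repulsion_approx(Y: Embedding, theta: float = 0.5) -> tuple[np.ndarray, float]:
    """Barnes-Hut approximate repulsive force numerators and Z estimate.

    Returns (F, Z) with F_i ~ sum_{j != i} w_ij^2 (y_i - y_j) and
    Z ~ sum_{k != l} w_kl; the repulsive gradient term is F / Z.  ``theta`` is
    the cell-opening threshold: a quadtree cell of side s at distance d is
    summarised by its centre of mass when s/d < theta, so theta = 0 reduces to
    the exact O(n^2) sum.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    Y = np.ascontiguousarray(Y, dtype=float)
    return _rep_barnes_hut(Y, float(theta))


# ---------------------------------------------------------------------------
# initialisation and schedules
# ---------------------------------------------------------------------------


def random_init(n: int, seed: int = 42) -> Embedding:
    """Gaussian random initialisation with standard deviation 1e-4."""
    rng = np.random.default_rng(seed)
    return 1e-4 * rng.standard_normal((n, 2))


def pca_init(scores: PCSpace | np.ndarray) -> Embedding:
    """First two PC scores scaled so that PC1 has standard deviation 1e-4.

    Injects the macroscopic arrangement of the data into the starting layout
    while keeping coordinates at the small magnitude optimisation needs.  The
    PC sign convention (loading sums nonnegative) makes this deterministic.
    """
    S = scores.scores if isinstance(scores, PCSpace) else np.asarray(scores, dtype=float)
    if S.shape[1] < 2:
        raise ValueError("need at least two principal components")
    Y = S[:, :2].copy()
    sd1 = Y[:, 0].std()
    if sd1 == 0:
        raise ValueError("first principal component is constant")
    return Y / sd1 * 1e-4


def rescale_init(Y: Embedding) -> Embedding:
    """Scale an arbitrary layout so its first coordinate has sd 1e-4.

    The same convention as PCA initialisation; used for downsampling-based and
    aligned initialisations.
    """
    Y = np.asarray(Y, dtype=float)
    sd1 = Y[:, 0].std()
    if sd1 == 0:
        raise ValueError("degenerate layout: first coordinate is constant")
    return Y / sd1 * 1e-4


def rotate_embedding(Y: Embedding, degrees: float, flip_horizontal: bool = False) -> Embedding:
    """Rigidly rotate (counter-clockwise) and optionally mirror a layout.

    Rotation and reflection are the only legitimate cosmetic adjustments of a
    finished embedding - they preserve all pairwise distances.  Stretching an
    axis does not, and is deliberately not offered.
    """
    t = np.deg2rad(degrees)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    out = np.asarray(Y, dtype=float) @ R.T
    if flip_horizontal:
        out = out * np.array([-1.0, 1.0])
    return out


def learning_rate_rule(n: int) -> float:
    """eta = n/12 whenever that exceeds the conventional default of 200."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(200.0, n / 12.0)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------


def optimize(
    P: AffinityMatrix | sp.spmatrix,
    init: Embedding,
    config: OptimizerConfig | None = None,
    callback: Callable[[int, Embedding], None] | None = None,
) -> Embedding:
    """Run adaptive gradient descent with momentum from ``init``.

    Attraction is exaggerated by ``config.early_exaggeration`` for the first
    ``early_exaggeration_iter`` iterations and by ``config.exaggeration``
    afterwards.  Repulsion is exact for n <= 5000 and Barnes-Hut above
    (``config.method`` overrides).  ``callback(iteration, Y)`` is invoked
    after every update, e.g. to record the loss.

    Raises
    ------
    RuntimeError
        On divergence (non-finite coordinates), citing eta and the iteration.
    """
    cfg = config or OptimizerConfig()
    Pc = _as_P(P)
    Y = np.array(init, dtype=float, copy=True)
    n = Y.shape[0]
    if Pc.shape[0] != n:
        raise ValueError(f"P is {Pc.shape[0]}x{Pc.shape[0]} but init has {n} rows")
    rms = float(np.sqrt((Y**2).mean()))
    if rms > 1e-2:
        warnings.warn(
            f"initial coordinates have rms {rms:.3g}; the optimiser expects "
            "magnitudes near 1e-4 (see rescale_init)",
            stacklevel=2,
        )
    use_bh = cfg.method == "bh" or (cfg.method == "auto" and n > _EXACT_MAX_N)
    logger.info(
        "t-SNE optimise: n=%d iters=%d eta=%g alpha_early=%g/%d alpha=%g %s",
        n, cfg.n_iter, cfg.eta, cfg.early_exaggeration,
        cfg.early_exaggeration_iter, cfg.exaggeration,
        "barnes-hut(theta=%g)" % cfg.theta if use_bh else "exact",
    )

    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    indptr, indices, data = Pc.indptr, Pc.indices, Pc.data
    for it in range(cfg.n_iter):
        alpha = (
            cfg.early_exaggeration
            if it < cfg.early_exaggeration_iter
            else cfg.exaggeration
        )
        momentum = (
            cfg.momentum_early if it < cfg.momentum_switch_iter else cfg.momentum_late
        )
        Fa = _attr_forces(indptr, indices, data, Y)
        if use_bh:
            Fr, Z = _rep_barnes_hut(Y, cfg.theta)
        else:
            Fr, Z = _rep_exact(Y)
        grad = alpha * Fa - Fr / Z
        agree = (grad > 0) == (update > 0)
        gains = np.where(agree, gains * 0.8, gains + 0.2)
        np.maximum(gains, 0.01, out=gains)
        update = momentum * update - cfg.eta * gains * grad
        Y += update
        if not np.all(np.isfinite(Y)):
            raise RuntimeError(
                f"t-SNE diverged at iteration {it} with eta={cfg.eta}; "
                "reduce the learning rate or rescale the initialisation"
            )
        if callback is not None:
            callback(it, Y)
    return Y
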