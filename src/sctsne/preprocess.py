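"""Standard scRNA-seq preprocessing ahead of embedding.

Fixed pipeline order: dropout-based feature selection on *raw* counts, then
sequencing-depth normalisation of the selected genes, log2(x+1) transform,
optional per-gene standardisation, and PCA down to 50 components.  Read counts
are normalised to counts-per-million; UMI counts to the median per-cell depth
(CPM-scaling UMI data would distort the subsequent log transform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneStats",
    "PCSpace",
    "normalize_depth",
    "gene_stats",
    "select_features",
    "log_transform",
    "arsinh_transform",
    "standardize",
    "reduce_pca",
    "preprocess_counts",
]


@dataclass
class CountMatrix:
    """Raw cell x gene counts with identifiers.

    ``counts`` may be dense or any scipy sparse matrix; ``count_kind`` is
    ``"umi"`` or ``"read"`` and controls both depth normalisation and the
    default near-zero threshold for feature selection.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    count_kind: Literal["umi", "read"] = "umi"

    def __post_init__(self) -> None:
        n, p = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} matrix columns")
        if self.count_kind not in ("umi", "read"):
            raise ValueError(f"count_kind must be 'umi' or 'read', got {self.count_kind!r}")
        if self.min() < 0:
            raise ValueError("counts must be nonnegative")

    def min(self) -> float:
        m = self.counts.min()
        return float(m)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class GeneStats:
    """Per-gene dropout fraction and mean log2 expression above threshold.

    ``d`` is the fraction of cells with count <= t (the near-zero/dropout
    fraction); ``m`` the mean log2 of counts strictly above t.  ``retained``
    flags genes expressed above t in at least ``n_min`` cells; ``d`` and ``m``
    are NaN for discarded genes.
    """

    d: np.ndarray
    m: np.ndarray
    t: float
    n_min: int
    retained: np.ndarray  # bool mask over genes


@dataclass
class PCSpace:
    """Principal-component scores and loadings with a deterministic sign.

    Components are ordered by decreasing explained variance, and each loading
    vector's entries sum to a nonnegative value (the vector is negated
    otherwise), which pins down the otherwise arbitrary PC signs.
    """

    scores: np.ndarray  # (n, n_components)
    components: np.ndarray  # (n_components, p) orthonormal rows
    explained_variance: np.ndarray  # (n_components,)


def default_threshold(count_kind: str) -> float:
    """Near-zero threshold t: 0 for UMI counts, 32 for read counts."""
    return 0.0 if count_kind == "umi" else 32.0


def normalize_depth(counts: CountMatrix) -> np.ndarray:
    """Depth-normalise: read counts to CPM, UMI counts to median cell depth.

    Returns a dense float matrix of the same shape.  Raises on any cell with
    zero total count (its scale factor is undefined), naming the cell.
    """
    X = counts.dense()
    depths = X.sum(axis=1)
    zero = np.flatnonzero(depths == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero sequencing depth: {[counts.cell_ids[i] for i in zero[:5]]}"
        )
    target = 1e6 if counts.count_kind == "read" else float(np.median(depths))
    return X * (target / depths)[:, None]


def gene_stats(counts: CountMatrix, t: float | None = None, n_min: int = 10) -> GeneStats:
    """Dropout fraction d_g and mean log2 above-threshold expression m_g.

    Operates on raw counts (feature selection precedes depth normalisation).
    Genes expressed above ``t`` in fewer than ``n_min`` cells are flagged as
    discarded.  ``t`` defaults by count kind (0 for UMI, 32 for reads).
    """
    if t is None:
        t = default_threshold(counts.count_kind)
    X = counts.dense()
    n = X.shape[0]
    above = X > t
    n_above = above.sum(axis=0)
    retained = n_above >= n_min
    d = above.mean(axis=0)
    d = 1.0 - d  # fraction of near-zero counts
    with np.errstate(divide="ignore", invalid="ignore"):
        logX = np.where(above, np.log2(np.where(above, X, 1.0)), 0.0)
        m = np.where(n_above > 0, logX.sum(axis=0) / np.maximum(n_above, 1), np.nan)
    d = np.where(retained, d, np.nan)
    m = np.where(retained, m, np.nan)
    return GeneStats(d=d, m=m, t=float(t), n_min=n_min, retained=retained)


def _count_selected(d: np.ndarray, m: np.ndarray, a: float, b: float) -> np.ndarray:
    return d > np.exp(-a * (m - b)) + 0.02


def select_features(stats: GeneStats, M: int, a: float = 1.5) -> tuple[np.ndarray, float]:
    """Select exactly ``M`` genes by the dropout-vs-mean-expression rule.

    A gene g is selected when ``d_g > exp(-a (m_g - b)) + 0.02``; the offset
    ``b`` is found by binary search so that exactly ``M`` genes satisfy the
    inequality (the count is non-increasing in b).  Returns the selected gene
    indices (into the original gene order) and the b found.  If ties make M
    unreachable, the nearest achievable count is returned with a warning.
    """
    mask = stats.retained
    d, m = stats.d[mask], stats.m[mask]
    idx = np.flatnonzero(mask)
    n_ret = idx.size
    if M > n_ret:
        raise ValueError(f"requested M={M} genes but only {n_ret} retained")
    if M == n_ret:
        b = -np.inf
    else:
        lo, hi = np.nanmin(m) - 60.0 / a, np.nanmax(m) + 60.0 / a
        # count(lo) ~ all selectable, count(hi) = 0; shrink the bracket on b
        b = None
        while hi - lo > 1e-10:
            mid = 0.5 * (lo + hi)
            c = int(_count_selected(d, m, a, mid).sum())
            if c == M:
                b = mid
                hi = mid  # keep going: ties broken by the smallest such b
            elif c > M:
                lo = mid
            else:
                hi = mid
        if b is None:
            b = hi
            c = int(_count_selected(d, m, a, b).sum())
            warnings.warn(
                f"no offset b selects exactly M={M} genes (ties/plateau); "
                f"returning nearest achievable count {c}",
                stacklevel=2,
            )
    sel = _count_selected(d, m, a, b) if np.isfinite(b) else np.ones(n_ret, bool)
    return idx[sel], float(b)


def log_transform(matrix: np.ndarray) -> np.ndarray:
    """Entrywise log2(x + 1); zeros stay zero.  Rejects negative input."""
    X = np.asarray(matrix, dtype=float)
    if X.min() < 0:
        raise ValueError("log transform requires nonnegative entries")
    return np.log2(X + 1.0)


def arsinh_transform(matrix: np.ndarray, r: float = 5.0) -> np.ndarray:
    """Inverse-hyperbolic-sine alternative: arsinh(x / r), r = 5 by default.

    Variance-stabilising for negative-binomial counts with dispersion r; not
    part of the default pipeline.
    """
    X = np.asarray(matrix, dtype=float)
    if X.min() < 0:
        raise ValueError("arsinh transform requires nonnegative entries")
    return np.arcsinh(X / r)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Centre each column and scale to unit variance.

    Constant columns are centred but left unscaled (they become all zeros),
    with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant column(s) centred but not scaled", stacklevel=2)
    return (X - mu) / np.where(const, 1.0, sd)


def reduce_pca(matrix: np.ndarray, n_components: int = 50) -> PCSpace:
    """PCA by economy SVD of the centred matrix, with a fixed sign rule.

    Each component whose loading entries sum to a negative value is negated
    (together with its scores), making the decomposition reproducible.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    flip = Vt.sum(axis=1) < 0
    Vt[flip] *= -1.0
    U[:, flip] *= -1.0
    return PCSpace(
        scores=U * s,
        components=Vt,
        explained_variance=s**2 / max(n - 1, 1),
    )


def preprocess_counts(
    counts: CountMatrix,
    n_genes: int = 1000,
    a: float = 1.5,
    t: float | None = None,
    n_min: int = 10,
    do_standardize: bool = False,
    transform: Literal["log", "arsinh"] = "log",
    n_components: int = 50,
) -> tuple[PCSpace, np.ndarray]:
    """Run the full preprocessing pipeline; returns (PCSpace, selected gene idx).

    Order is fixed: feature selection on raw counts -> depth normalisation ->
    log2(x+1) (or arsinh) -> optional standardisation -> PCA.
    """
    stats = gene_stats(counts, t=t, n_min=n_min)
    sel, _b = select_features(stats, M=min(n_genes, int(stats.retained.sum())), a=a)
    normed = normalize_depth(counts)[:, sel]
    X = log_transform(normed) if transform == "log" else arsinh_transform(normed)
    if do_standardize:
        X = standardize(X)
    k = min(n_components, min(X.shape))
    return reduce_pca(X, n_components=k), sel
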