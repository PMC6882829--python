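"""Out-of-sample mapping onto an existing embedding.

A new cell is placed at the coordinate-wise median embedding location of its
k = 10 most similar reference cells, with similarity measured as Pearson
correlation of log2-transformed expression across the genes shared between
query and reference (correlation distance is more robust to between-protocol
batch effects than Euclidean distance).  Mapping uncertainty is estimated by
bootstrapping over genes: repositioning on with-replacement gene resamples
and drawing a convex hull over the central 95% of bootstrap positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .tsne import Embedding, rescale_init

__all__ = [
    "ReferenceAtlas",
    "MappingResult",
    "position_cells",
    "loo_validation",
    "bootstrap_uncertainty",
    "aligned_init",
]


@dataclass
class ReferenceAtlas:
    """Reference embedding plus the log-expression matrix that produced it.

    ``log_expression`` holds log2(x+1)-transformed counts of the reference's
    selected (most variable) genes, one row per embedded cell.
    """

    embedding: np.ndarray  # (n_ref, 2)
    log_expression: np.ndarray  # (n_ref, L)
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.embedding.shape[0] != self.log_expression.shape[0]:
            raise ValueError("embedding and log_expression row counts differ")
        if self.log_expression.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match log_expression columns")
        if len(self.gene_ids) < 1:
            raise ValueError("atlas needs at least one gene")


@dataclass
class MappingResult:
    """Positions of query cells on the reference embedding."""

    positions: np.ndarray  # (n_query, 2)
    neighbor_ids: np.ndarray  # (n_query, k) reference row indices
    bootstrap_positions: np.ndarray | None = None  # (n_query, B, 2)
    hulls: list[np.ndarray] | None = None  # per-query hull vertices (m, 2)
    retained: list[np.ndarray] | None = None  # per-query retained bootstrap idx


def _match_genes(
    atlas: ReferenceAtlas, query_gene_ids: list[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Column indices (reference, query) of the shared genes, in atlas order."""
    if query_gene_ids is None:
        n = len(atlas.gene_ids)
        return np.arange(n), np.arange(n)
    qpos = {g: i for i, g in enumerate(query_gene_ids)}
    ref_cols, q_cols = [], []
    for i, g in enumerate(atlas.gene_ids):
        if g in qpos:
            ref_cols.append(i)
            q_cols.append(qpos[g])
    if not ref_cols:
        raise ValueError("query and reference share no genes")
    return np.asarray(ref_cols), np.asarray(q_cols)


def _center_norm(M: np.ndarray, what: str) -> np.ndarray:
    Mc = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Mc, axis=1)
    if what == "query" and np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(
            f"query cell {bad} has zero-variance expression; correlation undefined"
        )
    norms[norms == 0] = 1.0  # constant reference rows -> correlation 0
    return Mc / norms[:, None]


def _correlation_neighbors(
    ref_expr: np.ndarray,
    query_expr: np.ndarray,
    k: int,
    self_indices: np.ndarray | None,
) -> np.ndarray:
    """(n_query, k) reference indices by ascending 1 - Pearson correlation."""
    R = _center_norm(ref_expr, "reference")
    Q = _center_norm(query_expr, "query")
    D = 1.0 - Q @ R.T  # correlation distance
    if self_indices is not None:
        D[np.arange(D.shape[0]), self_indices] = np.inf
    order = np.argsort(D, axis=1, kind="stable")  # ties by reference index
    return order[:, :k]


def position_cells(
    atlas: ReferenceAtlas,
    query_log_expr: np.ndarray,
    k: int = 10,
    exclude_self: bool = False,
    query_gene_ids: list[str] | None = None,
) -> MappingResult:
    """Map query cells to the median location of their k most correlated
    reference cells.

    ``query_log_expr`` is cells x genes, log-transformed like the atlas.  With
    ``query_gene_ids`` given, only genes shared with the atlas are used (the
    reference's most variable genes present in the query).  ``exclude_self``
    treats query row i as a copy of reference row i and removes it from the
    candidates (leave-one-out validation).
    """
    ref_cols, q_cols = _match_genes(atlas, query_gene_ids)
    Q = np.asarray(query_log_expr, dtype=float)[:, q_cols]
    R = atlas.log_expression[:, ref_cols]
    if exclude_self and Q.shape[0] != R.shape[0]:
        raise ValueError("exclude_self requires one query row per reference row")
    self_idx = np.arange(Q.shape[0]) if exclude_self else None
    nbrs = _correlation_neighbors(R, Q, k, self_idx)
    positions = np.median(atlas.embedding[nbrs], axis=1)
    return MappingResult(positions=positions, neighbor_ids=nbrs)


def loo_validation(
    atlas: ReferenceAtlas, cell_subset: np.ndarray | None = None, k: int = 10
) -> np.ndarray:
    """Leave-one-out displacements: re-position atlas cells excluding
    themselves and return the Euclidean distance to their original location."""
    n = atlas.embedding.shape[0]
    subset = np.arange(n) if cell_subset is None else np.asarray(cell_subset)
    expr = atlas.log_expression
    R = _center_norm(expr, "reference")
    Q = _center_norm(expr[subset], "query")
    D = 1.0 - Q @ R.T
    D[np.arange(subset.size), subset] = np.inf
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    new_pos = np.median(atlas.embedding[order], axis=1)
    return np.linalg.norm(new_pos - atlas.embedding[subset], axis=1)


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex hull vertex coordinates; collinear input degenerates to the
    extreme segment endpoints."""
    uniq = np.unique(points, axis=0)
    if uniq.shape[0] < 3:
        return uniq
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except QhullError:  # collinear: return the segment spanning the spread
        c = points - points.mean(axis=0)
        direction = c[np.argmax(np.linalg.norm(c, axis=1))]
        t = c @ direction
        return points[[int(np.argmin(t)), int(np.argmax(t))]]


def bootstrap_uncertainty(
    atlas: ReferenceAtlas,
    query_log_expr: np.ndarray,
    B: int = 100,
    k: int = 10,
    seed: int = 42,
    query_gene_ids: list[str] | None = None,
) -> MappingResult:
    """Gene-bootstrap uncertainty hulls for query positions.

    Repositions each query ``B`` times on with-replacement resamples of the L
    shared genes, discards the 5% of bootstrap positions farthest (Euclidean)
    from the original mapping, and returns the convex hull of the rest (95
    positions retained for B = 100).
    """
    ref_cols, q_cols = _match_genes(atlas, query_gene_ids)
    L = ref_cols.size
    if L < 2:
        raise ValueError("bootstrapping needs at least 2 shared genes")
    Q = np.asarray(query_log_expr, dtype=float)[:, q_cols]
    R = atlas.log_expression[:, ref_cols]
    base = position_cells(atlas, query_log_expr, k=k, query_gene_ids=query_gene_ids)

    rng = np.random.default_rng(seed)
    nq = Q.shape[0]
    boot = np.empty((nq, B, 2))
    for b in range(B):
        cols = rng.integers(0, L, size=L)
        nbrs = _correlation_neighbors(R[:, cols], Q[:, cols], k, None)
        boot[:, b, :] = np.median(atlas.embedding[nbrs], axis=1)

    n_drop = int(round(0.05 * B))
    keep = B - n_drop
    hulls, retained = [], []
    for i in range(nq):
        dist = np.linalg.norm(boot[i] - base.positions[i], axis=1)
        kept = np.argsort(dist, kind="stable")[:keep]
        retained.append(kept)
        hulls.append(_hull_vertices(boot[i][kept]))
    return MappingResult(
        positions=base.positions,
        neighbor_ids=base.neighbor_ids,
        bootstrap_positions=boot,
        hulls=hulls,
        retained=retained,
    )


def aligned_init(
    atlas: ReferenceAtlas,
    new_log_expr: np.ndarray,
    k: int = 10,
    query_gene_ids: list[str] | None = None,
) -> Embedding:
    """Initialise a new embedding aligned to a reference atlas.

    All new cells are positioned on the reference and the layout is rescaled
    to the standard initialisation magnitude (first coordinate sd 1e-4); the
    subsequent t-SNE run then stays aligned with the reference.
    """
    mapped = position_cells(atlas, new_log_expr, k=k, query_gene_ids=query_gene_ids)
    return rescale_init(mapped.positions)
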