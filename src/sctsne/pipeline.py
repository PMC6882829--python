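"""End-to-end embedding recipes and file plumbing.

Two named recipes compose the other modules:

* the **standard protocol** (data sets up to ~100k cells): multi-scale
  similarities with perplexities {30, n/100} (n/100 combined in only when the
  sample is large enough for it to dominate 30), PCA initialisation, learning
  rate max(200, n/12), 1000 iterations, no late exaggeration;
* the **large-data protocol**: embed a random subsample with the standard
  protocol, position all remaining cells at the median location of their
  k = 10 Euclidean nearest subsample neighbours in PC space, rescale, and use
  that as initialisation for a full run with perplexity 30, learning rate
  n/12 and exaggeration 4.

File formats are plain text: Matrix Market with gene/barcode sidecars or
dense TSV for counts, TSV for embeddings and labels, JSON for reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .affinity import affinities_for
from .preprocess import CountMatrix, reduce_pca
from .quality import QualityReport, evaluate
from .tsne import (
    Embedding,
    OptimizerConfig,
    learning_rate_rule,
    optimize,
    pca_init,
    rescale_init,
)

__all__ = [
    "ProtocolParams",
    "resolve_perplexities",
    "run_standard",
    "run_large",
    "read_counts",
    "read_dense_tsv",
    "write_dense_tsv",
    "read_embedding",
    "write_embedding",
    "read_labels",
    "write_labels",
    "write_report",
    "read_config",
    "setup_logging",
]

logger = logging.getLogger("sctsne")


def setup_logging(quiet: bool = False) -> None:
    """Log progress to stderr with timestamps; ``quiet`` silences it."""
    logger.handlers.clear()
    if quiet:
        logger.addHandler(logging.NullHandler())
        return
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(h)
    logger.setLevel(logging.INFO)


@dataclass
class ProtocolParams:
    """Tunable parameters of the two recipes (defaults are the protocol)."""

    perplexity_base: float = 30.0
    multiscale_threshold: int = 6000  # combine n/100 with 30 from this n on
    subsample_size: int = 25000
    large_n_threshold: int = 100000
    exaggeration_large: float = 4.0
    k_position: int = 10
    n_iter: int = 1000
    theta: float = 0.5
    knn_k: int = 10
    knc_k: int = 10
    cpd_sample: int = 1000
    seed: int = 42


def resolve_perplexities(n: int, params: ProtocolParams | None = None) -> list[float]:
    """{30, n/100} when n/100 dwarfs 30 (n >= 6000), else {30} alone.

    The n/100 component is truncated to an integer.
    """
    p = params or ProtocolParams()
    base = p.perplexity_base
    if n >= p.multiscale_threshold:
        return [base, float(int(n / 100))]
    return [base]


def run_standard(
    X: np.ndarray,
    params: ProtocolParams | None = None,
    labels: np.ndarray | None = None,
    compute_quality: bool = True,
) -> tuple[Embedding, QualityReport | None]:
    """The standard protocol on an n x d matrix (typically 50 PC scores).

    Deterministic given the input: PCA initialisation removes any dependence
    on the random seed (the seed only enters the CPD subsample).
    """
    p = params or ProtocolParams()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n >= p.large_n_threshold:
        raise ValueError(
            f"n={n} is above large_n_threshold={p.large_n_threshold}; use run_large"
        )
    perplexities = resolve_perplexities(n, p)
    eta = learning_rate_rule(n)
    logger.info(
        "standard protocol: n=%d perplexities=%s eta=%g n_iter=%d seed=%d",
        n, perplexities, eta, p.n_iter, p.seed,
    )
    P = affinities_for(X, perplexities)
    init = pca_init(reduce_pca(X, n_components=2))
    cfg = OptimizerConfig(
        n_iter=p.n_iter, eta=eta, seed=p.seed, theta=p.theta,
        early_exaggeration_iter=min(250, p.n_iter // 4),
    )
    Y = optimize(P, init, cfg)
    report = None
    if compute_quality:
        report = evaluate(
            X, Y, labels=labels, knn_k=p.knn_k, knc_k=p.knc_k,
            cpd_sample=p.cpd_sample, seed=p.seed,
        )
        logger.info("quality: KNN=%.3f KNC=%.3f CPD=%.3f", report.knn, report.knc, report.cpd)
    return Y, report


def run_large(
    X: np.ndarray,
    params: ProtocolParams | None = None,
) -> Embedding:
    """The large-data protocol: downsample, embed, position, re-embed.

    (i) a seeded uniform subsample of ``subsample_size`` points; (ii) the
    standard protocol on the subsample; (iii) every remaining point placed at
    the coordinate-wise median embedding location of its ``k_position``
    Euclidean nearest subsample neighbours in the input (PC) space; (iv) the
    rescaled layout used to initialise a full-data run with perplexity 30,
    learning rate n/12 and exaggeration ``exaggeration_large``.
    """
    p = params or ProtocolParams()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if p.subsample_size > n:
        raise ValueError(f"subsample_size={p.subsample_size} exceeds n={n}")
    rng = np.random.default_rng(p.seed)
    sub = np.sort(rng.choice(n, size=p.subsample_size, replace=False))
    logger.info("large protocol: n=%d subsample=%d seed=%d", n, p.subsample_size, p.seed)

    sub_params = dataclasses.replace(
        p, large_n_threshold=max(p.large_n_threshold, p.subsample_size + 1)
    )
    Y_sub, _ = run_standard(X[sub], sub_params, compute_quality=False)

    rest = np.setdiff1d(np.arange(n), sub, assume_unique=True)
    init = np.empty((n, 2))
    init[sub] = Y_sub
    if rest.size:
        nn = NearestNeighbors(n_neighbors=p.k_position, algorithm="brute").fit(X[sub])
        _, nbrs = nn.kneighbors(X[rest])
        init[rest] = np.median(Y_sub[nbrs], axis=1)
    init = rescale_init(init)

    eta = learning_rate_rule(n)
    logger.info(
        "large protocol final run: perplexity=%g eta=%g exaggeration=%g",
        p.perplexity_base, eta, p.exaggeration_large,
    )
    P = affinities_for(X, [p.perplexity_base])
    cfg = OptimizerConfig(
        n_iter=p.n_iter, eta=eta, exaggeration=p.exaggeration_large,
        seed=p.seed, theta=p.theta,
        early_exaggeration_iter=min(250, p.n_iter // 4),
    )
    return optimize(P, init, cfg)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_ids(path: Path, what: str) -> list[str]:
    ids = [
        line.split("\t")[0].strip()
        for line in path.read_text().splitlines()
        if line.strip()
    ]
    if not ids:
        raise ValueError(f"{what} sidecar {path} is empty")
    return ids


def read_counts(
    counts_path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    kind: str = "umi",
) -> CountMatrix:
    """Read a count matrix: Matrix Market + sidecars, or dense TSV.

    For ``.mtx``, gene and barcode sidecars are required (defaults:
    ``genes.tsv`` / ``barcodes.tsv`` next to the matrix) and either matrix
    orientation is accepted — genes x cells input is transposed to the
    cells x genes convention based on the sidecar lengths.  A dense TSV has a
    header row of gene IDs and a first column of cell IDs.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else counts_path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else counts_path.parent / "barcodes.tsv"
        )
        try:
            M = scipy.io.mmread(counts_path)
        except Exception as e:  # noqa: BLE001 - add file context
            raise ValueError(f"malformed Matrix Market file {counts_path}: {e}") from e
        genes = _read_ids(genes_path, "gene")
        cells = _read_ids(barcodes_path, "barcode")
        M = sp.csr_matrix(M)
        if M.shape == (len(cells), len(genes)):
            pass
        elif M.shape == (len(genes), len(cells)):
            M = sp.csr_matrix(M.T)
        else:
            raise ValueError(
                f"matrix shape {M.shape} matches neither {len(cells)} barcodes x "
                f"{len(genes)} genes nor its transpose"
            )
        return CountMatrix(counts=M, gene_ids=genes, cell_ids=cells, count_kind=kind)
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    return CountMatrix(
        counts=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
        count_kind=kind,
    )


def read_dense_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Dense TSV (first column = row IDs) -> (matrix, row IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_dense_tsv(
    path: str | Path,
    M: np.ndarray,
    row_ids: list[str] | None = None,
    col_names: list[str] | None = None,
) -> None:
    M = np.asarray(M)
    if row_ids is None:
        row_ids = [f"cell{i}" for i in range(M.shape[0])]
    if col_names is None:
        col_names = [f"c{j}" for j in range(M.shape[1])]
    pd.DataFrame(M, index=row_ids, columns=col_names).to_csv(
        path, sep="\t", index_label="id", float_format="%.17g"
    )


def write_embedding(path: str | Path, Y: np.ndarray, cell_ids: list[str] | None = None) -> None:
    """Embedding TSV with columns cell_id, x, y."""
    write_dense_tsv(path, Y, row_ids=cell_ids, col_names=["x", "y"])


def read_embedding(path: str | Path) -> tuple[np.ndarray, list[str]]:
    return read_dense_tsv(path)


def write_labels(
    path: str | Path,
    cell_ids: list[str],
    type_labels: np.ndarray,
    class_labels: np.ndarray | None = None,
) -> None:
    df = pd.DataFrame({"cell_id": cell_ids, "type": np.asarray(type_labels)})
    if class_labels is not None:
        df["class"] = np.asarray(class_labels)
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "type" not in df.columns:
        raise ValueError(f"label file {path} lacks a 'type' column")
    return df


def write_report(path: str | Path, report: QualityReport) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file mirroring the CLI flags."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
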