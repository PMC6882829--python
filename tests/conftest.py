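import numpy as np
import pytest

from sctsne.preprocess import CountMatrix
from sctsne.syndata import ClassSpec, MixtureSpec, generate


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so results do
    # not depend on test execution order
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_mixture():
    """Three well-separated Gaussian types in 30 dimensions, 150 points each."""
    spec = MixtureSpec(
        dimension=30,
        classes=(ClassSpec(between_shift=0.0, within_shift=15.0, n_types=3, points_per_type=150),),
        seed=3,
    )
    return generate(spec)


@pytest.fixture()
def toy_counts():
    """A small UMI count matrix with a handful of informative genes."""
    rng = np.random.default_rng(7)
    n_cells, n_genes = 120, 40
    counts = rng.poisson(1.0, size=(n_cells, n_genes)).astype(float)
    counts[:, :5] += rng.poisson(20.0, size=(n_cells, 5))  # highly expressed genes
    counts[:60, 5:10] += rng.poisson(8.0, size=(60, 5))  # marker-like genes
    counts[0, :] += 1  # no zero-depth cells
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        count_kind="umi",
    )
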