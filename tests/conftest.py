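import numpy as np
import pytest
import scipy.sparse as sp

from codahd import CountMatrix


def random_counts(
    n_genes: int,
    n_cells: int,
    density: float = 0.3,
    max_count: int = 50,
    seed: int = 0,
    gene_prefix: str = "G",
) -> CountMatrix:
    """Random sparse integer count matrix; every cell has >= 1 count."""
    rng = np.random.default_rng(seed)
    M = sp.random(
        n_genes,
        n_cells,
        density=density,
        random_state=np.random.RandomState(seed),
        data_rvs=lambda n: rng.integers(1, max_count + 1, n).astype(float),
    ).tolil()
    # guarantee positive per-cell totals
    for j in range(n_cells):
        if M[:, j].nnz == 0:
            M[rng.integers(0, n_genes), j] = float(rng.integers(1, max_count + 1))
    return CountMatrix(
        M.tocsc(),
        [f"{gene_prefix}{i}" for i in range(n_genes)],
        [f"C{j}" for j in range(n_cells)],
    )


@pytest.fixture
def counts_factory():
    return random_counts


@pytest.fixture
def small_counts() -> CountMatrix:
    return random_counts(50, 20, seed=1)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 2 cells with hand-checkable totals (4, 9)."""
    vals = np.array([[0, 4], [1, 2], [3, 3]])
    return CountMatrix(sp.csc_matrix(vals), ["G0", "G1", "G2"], ["C0", "C1"])
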