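import numpy as np
import pytest
import scipy.sparse as sp

from atacsim import (
    BinByCellMatrix,
    ChromSizes,
    FixtureSpec,
    make_bins,
    make_fixture,
)


@pytest.fixture(scope="session")
def toy_bins3():
    """Three 5-kb bins on a 12-kb toy chromosome (last bin partial)."""
    return make_bins(ChromSizes((("chrT", 12000),)), 5000)


def matrix_from_dense(dense, bin_width=5000, barcodes=None):
    dense = np.asarray(dense)
    b, c = dense.shape
    bins = make_bins(ChromSizes((("chrT", b * bin_width),)), bin_width)
    if barcodes is None:
        barcodes = [f"bc{i}" for i in range(c)]
    return BinByCellMatrix(sp.csr_matrix(dense), bins, barcodes)


@pytest.fixture(scope="session")
def random_matrix():
    """A 200 x 40 sparse random count matrix for oracle comparisons."""
    rng = np.random.default_rng(42)
    dense = rng.poisson(0.5, size=(200, 40)) * (rng.random((200, 40)) < 0.3)
    return matrix_from_dense(dense)


@pytest.fixture(scope="session")
def small_fixture():
    """A small synthetic 'real' matrix with its generating profile."""
    return make_fixture(FixtureSpec(n_cells=300, n_bins=500, seed=11))
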