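import numpy as np
import pytest
import scipy.sparse as sp

from surrosai import Grid, OccurrenceMatrix


def make_matrix(dense, n_rows=1, n_cols=None):
    """Occurrence matrix from a dense 0/1 array of shape (species, cells)."""
    dense = np.asarray(dense, dtype=np.int8)
    n_species, n_cells = dense.shape
    if n_cols is None:
        n_cols = n_cells // n_rows
    assert n_rows * n_cols == n_cells
    return OccurrenceMatrix(
        grid=Grid(n_rows, n_cols),
        matrix=sp.csr_matrix(dense),
        species_ids=[f"s{j}" for j in range(n_species)],
    )


@pytest.fixture
def toy3():
    """Species A={c0,c1}, B={c1}, C={c2} on a 3-cell grid."""
    return make_matrix([[1, 1, 0], [0, 1, 0], [0, 0, 1]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


def random_instance(rng, n_species, n_cells, p=0.5, ensure_nonempty=True):
    """Random small incidence instance; every species occupies >= 1 cell."""
    while True:
        dense = (rng.random((n_species, n_cells)) < p).astype(np.int8)
        if not ensure_nonempty or dense.sum(axis=1).min() > 0:
            return make_matrix(dense)
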