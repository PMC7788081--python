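"""Shared pseudobulk sampling machinery.

A pseudobulk profile is the mean normalized expression of a random sample of
cells (default 30) from one population. Sampling is without replacement when
the population has at least ``size`` cells, otherwise with replacement.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def sample_cell_indices(
    n_cells: int, size: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_draws`` independent samples of ``size`` cell indices."""
    if n_cells == 0:
        raise ValueError("cannot sample from an empty population")
    if n_cells < size:
        return rng.integers(0, n_cells, size=(n_draws, size))
    # without replacement; batched via random-key argpartition for large draws
    if n_draws == 1:
        return rng.choice(n_cells, size=size, replace=False)[None, :]
    keys = rng.random((n_draws, n_cells))
    return np.argpartition(keys, size - 1, axis=1)[:, :size]


def pseudobulk_matrix(
    X: sp.spmatrix | np.ndarray,
    indices: np.ndarray,
) -> np.ndarray:
    """Mean expression for each row of ``indices`` over matrix ``X``.

    ``indices`` has shape (n_draws, size); the result is dense
    (n_draws, n_genes). Implemented as a sparse selection-matrix product so
    thousands of resamples stay cheap.
    """
    n_draws, size = indices.shape
    n_cells = X.shape[0]
    rows = np.repeat(np.arange(n_draws), size)
    sel = sp.csr_matrix(
        (np.full(indices.size, 1.0 / size), (rows, indices.ravel())),
        shape=(n_draws, n_cells),
    )
    out = sel @ X
    if sp.issparse(out):
        out = out.toarray()
    return np.asarray(out)
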