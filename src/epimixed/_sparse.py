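"""Small sparse-matrix helpers shared by the kinship and Gibbs machinery."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def dump_matrix(M, path, threshold: float = 0.0) -> None:
    """Write a matrix as 1-based coordinate triplets 'row col value'
    (debugging format; symmetric matrices are written in full)."""
    M = sp.coo_matrix(M)
    with open(path, "w") as fh:
        for i, j, v in zip(M.row, M.col, M.data):
            if abs(v) > threshold:
                fh.write(f"{i + 1} {j + 1} {float(v)!r}\n")


def csr_slots(U: sp.csr_matrix, rows, cols) -> np.ndarray:
    """Positions of (rows, cols) entries inside U.data.

    Every requested entry must exist in U's pattern; duplicates in
    (rows, cols) map to the same slot.
    """
    probe = sp.csr_matrix(
        (np.arange(1.0, U.nnz + 1.0), U.indices, U.indptr), shape=U.shape)
    slots = np.asarray(probe[np.asarray(rows), np.asarray(cols)]).ravel()
    slots = slots.astype(np.int64) - 1
    if (slots < 0).any():
        raise RuntimeError("sparsity pattern misses a requested entry")
    return slots
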