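"""KNN cell graph and the renormalized Laplacian smoothing filter.

The graph connects each cell to its k nearest neighbors in the standardized
expression space (Euclidean metric).  Smoothing uses the one-step generalized
Laplacian filter I - L_sym~ = D~^{-1/2} A~ D~^{-1/2} with the renormalization
trick A~ = I + A, which averages each cell's profile with its neighborhood and
damps high-frequency (cell-to-cell) noise.

The KNN rule is directed (row i marks i's neighbors); the filter operates on
the symmetrized graph max(A, A^T) since the smoothing operator is defined for
an undirected graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

__all__ = ["CellGraph", "knn_graph", "from_adjacency", "laplacian_filter"]


@dataclass
class CellGraph:
    adjacency: sparse.csr_matrix  # directed KNN rule, row-wise
    adjacency_sym: sparse.csr_matrix  # max(A, A^T), used by the filter
    k: int
    degrees: np.ndarray  # row sums of the directed adjacency (== k each)
    renormalized_operator: sparse.csr_matrix  # D~^{-1/2} (I + A_sym) D~^{-1/2}

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


def knn_graph(X, k: int) -> CellGraph:
    """Build the k-nearest-neighbor graph of the rows of ``X``.

    ``A[i, j] = 1`` iff j is among the k nearest neighbors of i (self
    excluded).  Distance ties are broken toward the lower cell index, which
    together with exact (non-approximate) search makes construction fully
    deterministic.
    """
    X = np.asarray(getattr(X, "values", X), dtype=np.float64)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells; got k={k}, n={n}")
    # exact pairwise distances; stable argsort implements the tie-break
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)  # exclude self
    order = np.argsort(d2, axis=1, kind="stable")
    neighbors = order[:, :k]

    rows = np.repeat(np.arange(n), k)
    cols = neighbors.ravel()
    A = sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    A_sym = A.maximum(A.T).tocsr()
    A_tilde = (sparse.identity(n, format="csr") + A_sym).tocsr()
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
    op = (d_inv_sqrt @ A_tilde @ d_inv_sqrt).tocsr()
    return CellGraph(
        adjacency=A,
        adjacency_sym=A_sym,
        k=k,
        degrees=np.asarray(A.sum(axis=1)).ravel(),
        renormalized_operator=op,
    )


def from_adjacency(A, k: int = 0) -> CellGraph:
    """Build a :class:`CellGraph` from an explicit 0/1 adjacency matrix
    (row-wise, possibly asymmetric); the smoothing operator is formed on the
    symmetrized graph exactly as in :func:`knn_graph`."""
    A = sparse.csr_matrix(A)
    if (A.diagonal() != 0).any():
        raise ValueError("adjacency diagonal must be zero")
    n = A.shape[0]
    A_sym = A.maximum(A.T).tocsr()
    A_tilde = (sparse.identity(n, format="csr") + A_sym).tocsr()
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sparse.diags(1.0 / np.sqrt(deg))
    op = (d_inv_sqrt @ A_tilde @ d_inv_sqrt).tocsr()
    return CellGraph(
        adjacency=A,
        adjacency_sym=A_sym,
        k=k,
        degrees=np.asarray(A.sum(axis=1)).ravel(),
        renormalized_operator=op,
    )


def laplacian_filter(g: CellGraph, X) -> np.ndarray:
    """Apply one pass of the smoothing filter: D~^{-1/2} A~ D~^{-1/2} X."""
    X = np.asarray(getattr(X, "values", X), dtype=np.float64)
    if X.shape[0] != g.n_cells:
        raise ValueError(
            f"X has {X.shape[0]} rows but the graph was built on {g.n_cells} cells"
        )
    return np.asarray(g.renormalized_operator @ X)


def export_edge_list(g: CellGraph, path: str | Path) -> None:
    """Write the directed KNN edges as a TSV (source, target)."""
    coo = g.adjacency.tocoo()
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{i}\t{j}\n")
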