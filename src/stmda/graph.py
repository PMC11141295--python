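"""Spatial k-nearest-neighbor graph with expression-similarity weights.

The graph couples the spatial and expression views: edges follow spatial
proximity (Euclidean kNN on coordinates) while edge weights follow
transcriptional similarity of the connected spots, measured on a PCA
embedding of expression.  Weighted edges are column-normalized, then the
graph is symmetrized and renormalized as D̃^{-1/2}(A + I)D̃^{-1/2} for use
by the graph-convolutional branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .exceptions import ParameterError
from .preprocessing import PCAEmbedding

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialGraph",
    "spatial_knn",
    "similarity_weights",
    "normalize_adjacency",
    "build_spatial_graph",
]


@dataclass
class SpatialGraph:
    """kNN spatial graph with similarity weights and GCN normalization.

    Attributes
    ----------
    neighbors:
        (N, k) integer array; row i lists the k nearest spatial neighbors of
        spot i (self excluded), nearest first, distance ties broken by lower
        spot index.
    A:
        N x N sparse weight matrix; each column sums to 1 over its support.
    A_norm:
        D̃^{-1/2}(A_sym + I)D̃^{-1/2} with A_sym = (A + Aᵀ)/2; symmetric.
    k:
        Neighborhood size.
    """

    neighbors: np.ndarray
    A: sp.csr_matrix
    A_norm: sp.csr_matrix
    k: int


def spatial_knn(coords: np.ndarray, k: int) -> np.ndarray:
    """k nearest spots by Euclidean distance, ties broken by lower index.

    Returns an (N, k) integer array ordered nearest-first.  Brute force with
    a stable (distance, index) sort so results are fully deterministic even
    with duplicate coordinates; computed in row chunks to bound memory.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the number of spots {n}")
    neighbors = np.empty((n, k), dtype=np.int64)
    idx = np.arange(n)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = (
            np.sum(coords[start:stop] ** 2, axis=1)[:, None]
            + np.sum(coords**2, axis=1)[None, :]
            - 2.0 * coords[start:stop] @ coords.T
        )
        d2[idx[start:stop] - start, idx[start:stop]] = np.inf  # exclude self
        for row in range(stop - start):
            order = np.lexsort((idx, d2[row]))
            neighbors[start + row] = order[:k]
    return neighbors


def similarity_weights(
    U: PCAEmbedding | np.ndarray,
    neighbors: np.ndarray,
    convention: str = "cosine_distance",
) -> sp.csr_matrix:
    """Expression-similarity weights on the spatial kNN edges.

    For each edge (i, j) the weight before normalization is
    ``D_ij = exp(2 - d)`` where, under the default ``cosine_distance``
    convention, ``d = 1 - cos(U_i, U_j)`` (in [0, 2], so identical
    neighbors get e^2 and opposite ones get e^0 = 1); under ``as_printed``
    the exponent uses the raw cosine, ``d = cos(U_i, U_j)``.  Weights are
    then normalized so each column sums to 1 over its neighbor support.
    """
    if convention not in ("cosine_distance", "as_printed"):
        raise ParameterError(f"unknown similarity convention {convention!r}")
    scores = U.U if isinstance(U, PCAEmbedding) else np.asarray(U, dtype=np.float64)
    n = scores.shape[1]
    neighbors = np.asarray(neighbors)
    if neighbors.shape[0] != n:
        raise ParameterError("neighbor list rows must match number of spots")

    norms = np.linalg.norm(scores, axis=0)
    zero_norm = norms == 0
    if np.any(zero_norm):
        logger.warning(
            "%d spot(s) have zero-norm PC vectors; their similarities are 0",
            int(zero_norm.sum()),
        )
    safe = np.where(zero_norm, 1.0, norms)
    unit = scores / safe

    rows = np.repeat(np.arange(n), neighbors.shape[1])
    cols = neighbors.ravel()
    cos = np.einsum("di,di->i", unit[:, rows], unit[:, cols])
    cos[zero_norm[rows] | zero_norm[cols]] = np.nan  # mark degenerate pairs
    if convention == "cosine_distance":
        d = 1.0 - cos
    else:
        d = cos
    weights = np.exp(2.0 - d)
    weights[np.isnan(weights)] = 0.0

    D = sp.csr_matrix((weights, (rows, cols)), shape=(n, n))
    col_sums = np.asarray(D.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0
    A = D @ sp.diags(1.0 / col_sums)
    return sp.csr_matrix(A)


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric GCN normalization D̃^{-1/2}(A_sym + I)D̃^{-1/2}.

    The kNN relation is asymmetric, so A is first symmetrized by averaging
    with its transpose; self-loops are then added and both sides scaled by
    the inverse square root of the degree.  Row sums are >= 1 after adding
    I, so the normalization is always well defined.
    """
    A = sp.csr_matrix(A)
    if (A.data < 0).any():
        raise ParameterError("adjacency weights must be non-negative")
    A_sym = (A + A.T) * 0.5
    A_tilde = A_sym + sp.identity(A.shape[0], format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    out = sp.csr_matrix(inv_sqrt @ A_tilde @ inv_sqrt)
    if not np.all(np.isfinite(out.data)):
        raise ParameterError("normalized adjacency contains non-finite entries")
    return out


def build_spatial_graph(
    coords: np.ndarray,
    U: PCAEmbedding | np.ndarray,
    k: int = 6,
    convention: str = "cosine_distance",
) -> SpatialGraph:
    """Convenience constructor: kNN -> similarity weights -> normalization."""
    neighbors = spatial_knn(coords, k)
    A = similarity_weights(U, neighbors, convention=convention)
    return SpatialGraph(neighbors=neighbors, A=A, A_norm=normalize_adjacency(A), k=k)
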