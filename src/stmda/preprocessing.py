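"""Expression preprocessing: HVG selection, log transform, PCA embedding.

The pipeline mirrors standard SRT practice: select the top highly variable
genes on raw counts (Seurat-style dispersion on log data), log1p-transform,
then take a low-dimensional PCA of the result to drive spatial-graph
similarity weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scanpy as sc

from .datasets import SRTDataset
from .exceptions import ParameterError, StmdaError

__all__ = ["PCAEmbedding", "select_hvgs", "log1p_transform", "compute_pca"]


@dataclass
class PCAEmbedding:
    """Principal-component scores of the (log) expression matrix.

    ``U`` is n_pcs x N: column i is the PC score vector of spot i.
    """

    U: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.U.shape[0]


def select_hvgs(ds: SRTDataset, n_top: int = 3000) -> SRTDataset:
    """Restrict the dataset to the top highly variable genes.

    Uses the Seurat-flavor dispersion criterion (scanpy's default) computed
    on log1p counts.  If the dataset has fewer than ``n_top`` genes, all
    genes are kept with a warning.  Input gene order is preserved.
    """
    if n_top <= 0:
        raise ParameterError(f"n_top must be positive, got {n_top}")
    if ds.log_transformed:
        raise StmdaError("select_hvgs expects raw counts")
    if ds.n_genes <= n_top:
        if ds.n_genes < n_top:
            warnings.warn(
                f"requested {n_top} HVGs but only {ds.n_genes} genes present; "
                "keeping all genes",
                stacklevel=2,
            )
        return ds
    adata = ds.to_anndata()
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    # Rank by the raw Seurat dispersion statistic rather than the
    # bin-normalized one: mean-binned z-scoring degenerates when few genes
    # share a bin (normalizing markers only against each other), and an
    # exact top-n selection avoids cutoff ties.  Stable sort keeps input
    # gene order as the tie-break.
    disp = adata.var["dispersions"].to_numpy()
    disp = np.where(np.isfinite(disp), disp, -np.inf)
    top = np.sort(np.argsort(-disp, kind="stable")[:n_top])
    return ds.subset_genes(top)


def log1p_transform(ds: SRTDataset) -> SRTDataset:
    """Entrywise log(1 + x); guards against double transformation."""
    if ds.log_transformed:
        raise StmdaError("expression is already log-transformed")
    return replace(ds, expression=np.log1p(ds.expression), log_transformed=True)


def compute_pca(ds: SRTDataset, n_pcs: int = 15) -> PCAEmbedding:
    """Per-gene-centered PCA of log expression, deterministic sign.

    Sign indeterminacy is fixed by forcing the largest-magnitude gene
    loading of each component to be positive, so results are reproducible
    across runs and BLAS builds.
    """
    if n_pcs <= 0:
        raise ParameterError(f"n_pcs must be positive, got {n_pcs}")
    if not ds.log_transformed:
        raise StmdaError("compute_pca expects log-transformed expression")
    m, n = ds.expression.shape
    if n_pcs > min(m, n):
        raise ParameterError(f"n_pcs={n_pcs} exceeds min(M, N)={min(m, n)}")

    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(ds.expression.T)  # spots x n_pcs
    components = pca.components_  # n_pcs x genes
    flip = np.sign(
        components[np.arange(n_pcs), np.argmax(np.abs(components), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    return PCAEmbedding(
        U=scores.T.copy(), explained_variance=pca.explained_variance_.copy()
    )
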