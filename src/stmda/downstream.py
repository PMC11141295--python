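"""Spatial-domain calling and evaluation metrics.

The joint latent representation is clustered by Leiden community detection
on a kNN graph; when a target domain count is given, the resolution is
found by bisection.  Evaluation follows common SRT practice: ARI / purity
against reference labels, silhouette and Davies-Bouldin computed on the
spatial coordinates (spatial coherence, not embedding compactness),
Moran's I for spatial autocorrelation of per-gene expression, and
domain-wise log fold change for expression specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, ShapeError, StmdaError
from .graph import spatial_knn

logger = logging.getLogger(__name__)

__all__ = [
    "DomainResult",
    "cluster_embedding",
    "ari",
    "purity",
    "silhouette_spatial",
    "davies_bouldin_spatial",
    "morans_i",
    "domain_log_fold_change",
    "filter_degs",
    "denoise",
]


@dataclass
class DomainResult:
    """Cluster labels plus the artifacts downstream consumers need."""

    labels: np.ndarray
    embedding: np.ndarray  # latent_dim x N
    denoised: np.ndarray | None
    resolution_used: float
    spot_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    target_reached: bool = True
    metrics: dict = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return int(self.labels.max()) + 1


def _leiden_once(adata, resolution: float, seed: int) -> np.ndarray:
    import warnings

    import scanpy as sc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            key_added="domain",
            flavor="leidenalg",
        )
    return adata.obs["domain"].astype(int).to_numpy()


def _densify_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..n-1 in order of first appearance."""
    _, dense = np.unique(labels, return_inverse=True)
    return dense.astype(np.int64)


def cluster_embedding(
    H: np.ndarray,
    n_neighbors: int = 15,
    target_domains: int | None = None,
    resolution: float | None = None,
    seed: int = 0,
) -> DomainResult:
    """Leiden clustering of the joint embedding columns.

    Exactly one of ``target_domains`` / ``resolution`` must be given.  With
    a target count, the resolution is bisection-searched in [0.01, 5.0]
    (<= 40 iterations); if the exact count is unreachable, the closest
    achieved labeling is returned with ``target_reached=False``.
    """
    if (target_domains is None) == (resolution is None):
        raise ParameterError("give exactly one of target_domains / resolution")
    import anndata as ad
    import scanpy as sc

    H = np.asarray(H, dtype=np.float64)
    adata = ad.AnnData(X=H.T.copy())
    n_neighbors = min(n_neighbors, H.shape[1] - 1)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X",
                    random_state=seed)

    if resolution is not None:
        labels = _densify_labels(_leiden_once(adata, resolution, seed))
        return DomainResult(
            labels=labels, embedding=H, denoised=None, resolution_used=resolution
        )

    lo, hi = 0.01, 5.0
    best = None  # (count_gap, resolution, labels)
    reached = False
    res = None
    for _ in range(40):
        res = 0.5 * (lo + hi)
        labels = _leiden_once(adata, res, seed)
        count = len(np.unique(labels))
        gap = abs(count - target_domains)
        if best is None or gap < best[0]:
            best = (gap, res, labels)
        if count == target_domains:
            reached = True
            break
        if count < target_domains:
            lo = res
        else:
            hi = res
    if not reached:
        logger.warning(
            "bisection could not reach %d domains; returning closest (%d)",
            target_domains, len(np.unique(best[2])),
        )
    gap, res, labels = best
    return DomainResult(
        labels=_densify_labels(labels),
        embedding=H,
        denoised=None,
        resolution_used=res,
        target_reached=reached,
    )


def ari(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index (permutation-model chance correction)."""
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.shape != labels_b.shape:
        raise ShapeError("label vectors differ in length")
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))


def purity(labels: np.ndarray, reference: np.ndarray) -> float:
    """Fraction of spots in the majority reference class of their cluster."""
    labels = np.asarray(labels).ravel()
    reference = np.asarray(reference).ravel()
    if labels.shape != reference.shape:
        raise ShapeError("label vectors differ in length")
    total = 0
    for lab in np.unique(labels):
        ref_in = reference[labels == lab]
        _, counts = np.unique(ref_in, return_counts=True)
        total += counts.max()
    return float(total) / labels.size


def silhouette_spatial(labels: np.ndarray, coords: np.ndarray) -> float:
    """Mean silhouette over spots, on Euclidean distances between spatial
    coordinates (a spatial-coherence score, not an embedding score)."""
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise StmdaError("silhouette undefined for a single cluster")
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(np.asarray(coords, dtype=np.float64), labels))


def davies_bouldin_spatial(labels: np.ndarray, coords: np.ndarray) -> float:
    """Davies-Bouldin index on spatial coordinates; lower is better."""
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise StmdaError("Davies-Bouldin undefined for a single cluster")
    from sklearn.metrics import davies_bouldin_score

    return float(davies_bouldin_score(np.asarray(coords, dtype=np.float64), labels))


def morans_i(values: np.ndarray, coords: np.ndarray, k: int = 6) -> float:
    """Moran's I spatial autocorrelation with binary kNN weights.

    I = (N / W) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with z the centered
    values and w the (asymmetric) binary spatial kNN adjacency — the same
    neighborhood definition the model's spatial graph uses.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    z = values - values.mean()
    denom = np.sum(z**2)
    if denom == 0:
        raise StmdaError("Moran's I undefined for a constant vector")
    neighbors = spatial_knn(np.asarray(coords, dtype=np.float64), k)
    w_total = neighbors.size
    num = np.sum(z[:, None] * z[neighbors])
    return float((n / w_total) * (num / denom))


def domain_log_fold_change(
    expr: np.ndarray, labels: np.ndarray, domain: int, eps: float = 1e-9
) -> np.ndarray:
    """Per-gene log2 of (mean inside domain + eps) / (mean outside + eps)."""
    expr = np.asarray(expr, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    inside = labels == domain
    if not inside.any():
        raise ParameterError(f"domain {domain} not present in labels")
    if inside.all():
        raise ParameterError("log fold change needs a non-empty out-group")
    mean_in = expr[:, inside].mean(axis=1)
    mean_out = expr[:, ~inside].mean(axis=1)
    return np.log2((mean_in + eps) / (mean_out + eps))


def filter_degs(
    expr: np.ndarray, labels: np.ndarray, domain: int, threshold: float = 1.0
) -> np.ndarray:
    """Indices of genes whose domain log fold change exceeds ``threshold``."""
    lfc = domain_log_fold_change(expr, labels, domain)
    return np.flatnonzero(lfc > threshold)


def denoise(fit_result) -> np.ndarray:
    """Eval-mode reconstructed expression (the decoder output from the
    mean-based joint representation)."""
    return fit_result.denoised
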