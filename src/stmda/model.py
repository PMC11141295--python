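"""The stMDA estimator: preprocessing, graph building, training and
clustering behind a scikit-learn-style fit/transform interface."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .datasets import SRTDataset
from .exceptions import ParameterError
from .graph import build_spatial_graph
from .losses import MMDConfig
from .preprocessing import compute_pca, log1p_transform, select_hvgs
from .training import TrainConfig, fit as _train

__all__ = ["STMDA"]


class STMDA(BaseEstimator):
    """Multi-modal domain adaptation for spatial transcriptomics.

    Integrates gene expression, spatial coordinates and (optional) per-spot
    image features into a joint latent representation by aligning the
    per-layer distributions of three modality-specific encoders with
    maximum mean discrepancy, and reconstructs expression through a shared
    decoder for denoising.

    Parameters
    ----------
    n_top_hvgs:
        Number of highly variable genes to keep (all genes if fewer).
    n_pcs:
        Principal components used for graph similarity weighting.
    knn_k:
        Spatial nearest-neighbor count (6 matches the hexagonal Visium
        neighborhood).
    hidden_dim, latent_dim:
        Encoder widths: input -> hidden_dim -> latent_dim.
    lambda_align:
        Weight of the global + local alignment losses; 0 disables alignment.
    epochs, learning_rate:
        Full-batch Adam settings.
    use_image, use_spatial, use_deep_alignment, use_any_alignment:
        Ablation switches (image branch; GCN + local alignment; per-layer
        vs final-layer alignment; alignment at all).
    similarity_convention:
        Edge-weight convention, ``"cosine_distance"`` (monotone in
        similarity) or ``"as_printed"``.
    mmd_estimator:
        ``"standard_biased"`` or ``"as_printed"``.
    normalize_total:
        Library-size normalize counts before log1p (off by default).
    n_neighbors:
        kNN size of the embedding graph used for Leiden clustering.
    random_state:
        Seed for initialization, sampling and clustering.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_spots, latent_dim)
        Joint latent representation (eval mode).
    denoised_ : ndarray of shape (n_genes_kept, n_spots)
        Reconstructed (denoised) log1p expression.
    labels_ : ndarray of shape (n_spots,)
        Spatial-domain labels (set by :meth:`fit_predict`).
    loss_history_ : list of dict
        Per-epoch loss components.
    """

    def __init__(
        self,
        n_top_hvgs: int = 3000,
        n_pcs: int = 15,
        knn_k: int = 6,
        hidden_dim: int = 128,
        latent_dim: int = 10,
        lambda_align: float = 1.0,
        epochs: int = 500,
        learning_rate: float = 1e-3,
        use_image: bool = True,
        use_spatial: bool = True,
        use_deep_alignment: bool = True,
        use_any_alignment: bool = True,
        similarity_convention: str = "cosine_distance",
        mmd_estimator: str = "standard_biased",
        normalize_total: bool = False,
        n_neighbors: int = 15,
        random_state: int = 0,
    ):
        self.n_top_hvgs = n_top_hvgs
        self.n_pcs = n_pcs
        self.knn_k = knn_k
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.lambda_align = lambda_align
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.use_image = use_image
        self.use_spatial = use_spatial
        self.use_deep_alignment = use_deep_alignment
        self.use_any_alignment = use_any_alignment
        self.similarity_convention = similarity_convention
        self.mmd_estimator = mmd_estimator
        self.normalize_total = normalize_total
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X: SRTDataset, y=None) -> "STMDA":
        """Preprocess, build the spatial graph and train on a dataset."""
        if not isinstance(X, SRTDataset):
            raise ParameterError(
                "STMDA.fit expects an SRTDataset (see stmda.datasets)"
            )
        ds = X.drop_empty_spots()
        if not ds.log_transformed:
            ds = select_hvgs(ds, self.n_top_hvgs)
            if self.normalize_total:
                totals = ds.expression.sum(axis=0, keepdims=True)
                median = np.median(totals)
                from dataclasses import replace

                ds = replace(ds, expression=ds.expression / totals * median)
            ds = log1p_transform(ds)

        graph = None
        if self.use_spatial:
            pcs = compute_pca(ds, n_pcs=min(self.n_pcs,
                                            min(ds.n_genes, ds.n_spots)))
            graph = build_spatial_graph(
                ds.coords, pcs, k=self.knn_k,
                convention=self.similarity_convention,
            )

        cfg = TrainConfig(
            hidden_dim=self.hidden_dim,
            latent_dim=self.latent_dim,
            lambda_align=self.lambda_align,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            seed=self.random_state,
            use_image=self.use_image,
            use_spatial=self.use_spatial,
            use_deep_alignment=self.use_deep_alignment,
            use_any_alignment=self.use_any_alignment,
            mmd=MMDConfig(estimator=self.mmd_estimator),
        )
        result = _train(ds, graph, None, cfg)

        self.dataset_ = ds
        self.graph_ = graph
        self.fit_result_ = result
        self.embedding_ = result.embedding.T.copy()  # spots x latent
        self.denoised_ = result.denoised
        self.loss_history_ = result.loss_history
        self.attention_weights_ = result.stack.alphas
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the (n_spots, latent_dim) joint embedding of the fit data."""
        self._check_fitted()
        return self.embedding_

    def fit_transform(self, X: SRTDataset, y=None) -> np.ndarray:
        return self.fit(X, y).transform()

    def fit_predict(
        self,
        X: SRTDataset,
        y=None,
        target_domains: int | None = None,
        resolution: float | None = None,
    ) -> np.ndarray:
        """Fit, then cluster the joint embedding into spatial domains."""
        self.fit(X, y)
        return self.predict_domains(
            target_domains=target_domains, resolution=resolution
        )

    def predict_domains(
        self,
        target_domains: int | None = None,
        resolution: float | None = None,
    ) -> np.ndarray:
        """Leiden-cluster the fitted embedding; sets ``labels_``."""
        self._check_fitted()
        from .downstream import cluster_embedding

        if target_domains is None and resolution is None:
            resolution = 1.0
        result = cluster_embedding(
            self.fit_result_.embedding,
            n_neighbors=self.n_neighbors,
            target_domains=target_domains,
            resolution=resolution,
            seed=self.random_state,
        )
        result.denoised = self.denoised_
        result.spot_ids = list(self.dataset_.spot_ids)
        result.gene_ids = list(self.dataset_.gene_ids)
        self.labels_ = result.labels
        self.domain_result_ = result
        return result.labels

    def _check_fitted(self) -> None:
        if not hasattr(self, "fit_result_"):
            raise ParameterError("this STMDA instance is not fitted yet")
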