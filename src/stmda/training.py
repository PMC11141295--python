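"""The full training objective and optimization loop.

The loss is the VAE evidence lower bound (Gaussian likelihood on log1p
expression, standard-normal latent prior) plus lambda times the sum of the
global and spatially local alignment losses:

    L = recon + KL + lambda * (Loss_align_D + Loss_align_SD)

Optimization is full-batch Adam with its usual defaults (lr 1e-3,
betas (0.9, 0.999), eps 1e-8); everything is seeded so a fit reproduces
its loss trajectory exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor
from .datasets import SRTDataset
from .exceptions import ParameterError, StmdaError
from .graph import SpatialGraph
from .images import standardize_features
from .losses import (
    MMDConfig,
    kernel_gram,
    local_alignment_from_grams,
    mmd2_from_grams,
)
from .networks import (
    AttentionFusion,
    BranchSpec,
    Decoder,
    DecoderSpec,
    GCNBranch,
    MLPBranch,
    ModalityStack,
    VAEBranch,
)

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "FitResult", "elbo_loss", "total_loss", "fit",
           "select_lambda"]

# spots beyond which the local loss subsamples spots per step
_LOCAL_FULL_SUM_LIMIT = 2000
_LOCAL_SUBSAMPLE = 512


@dataclass
class TrainConfig:
    """Architecture, objective and optimization settings."""

    hidden_dim: int = 128
    latent_dim: int = 10
    attention_hidden: int | None = None  # default: latent_dim
    activation: str = "elu"
    lambda_align: float = 1.0
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    use_image: bool = True
    use_spatial: bool = True
    use_deep_alignment: bool = True
    use_any_alignment: bool = True
    mmd: MMDConfig = field(default_factory=MMDConfig)
    local_subsample: int | None = None  # None = auto

    def __post_init__(self):
        if self.lambda_align < 0:
            raise ParameterError("lambda_align must be >= 0")
        if self.epochs <= 0:
            raise ParameterError("epochs must be positive")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")


@dataclass
class FitResult:
    """Converged model outputs in eval mode."""

    stack: ModalityStack
    denoised: np.ndarray  # M x N reconstructed expression
    loss_history: list[dict]
    config: TrainConfig
    seed: int

    @property
    def embedding(self) -> np.ndarray:
        """latent_dim x N joint representation H."""
        return self.stack.H


def elbo_loss(
    X1: np.ndarray, X1_hat: np.ndarray, mu: np.ndarray, logvar: np.ndarray
) -> tuple[float, float]:
    """(reconstruction, KL) of the ELBO with a unit-variance Gaussian
    likelihood and standard-normal prior.

    Reconstruction is the squared error summed over genes and averaged over
    spots; KL is averaged over spots.
    """
    X1 = np.asarray(X1, dtype=np.float64)
    diff = X1 - np.asarray(X1_hat, dtype=np.float64)
    n = X1.shape[1]
    recon = float(np.sum(diff**2) / n)
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    kl = float(0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0) / mu.shape[1])
    return recon, kl


def total_loss(
    elbo: tuple[float, float],
    align_global: float,
    align_local: float,
    cfg: TrainConfig,
) -> float:
    """Compose the overall objective; lambda 0 (or the all-alignment
    ablation) reduces it to the ELBO alone."""
    recon, kl = elbo
    lam = cfg.lambda_align if cfg.use_any_alignment else 0.0
    return recon + kl + lam * (align_global + align_local)


class _Adam:
    """Adam with the standard defaults, operating on parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class _Model:
    """The assembled branches, fusion and decoder for one dataset."""

    def __init__(self, n_genes: int, n_feat: int | None, cfg: TrainConfig,
                 rng: np.random.Generator):
        enc = [n_genes, cfg.hidden_dim, cfg.latent_dim]
        spec1 = BranchSpec(list(enc), activation=cfg.activation)
        self.spec = spec1
        self.gcn = (GCNBranch(spec1, rng) if cfg.use_spatial
                    else MLPBranch(spec1, rng))
        self.vae = VAEBranch(BranchSpec(list(enc), activation=cfg.activation), rng)
        self.img = None
        if cfg.use_image and n_feat is not None:
            self.img = MLPBranch(
                BranchSpec([n_feat, cfg.hidden_dim, cfg.latent_dim],
                           activation=cfg.activation), rng)
        n_mod = 2 + (self.img is not None)
        self.attention = (AttentionFusion(cfg.latent_dim, rng,
                                          cfg.attention_hidden)
                          if n_mod > 1 else None)
        self.decoder = Decoder(
            DecoderSpec([cfg.latent_dim, cfg.hidden_dim, n_genes],
                        activation=cfg.activation), rng)
        self.cfg = cfg

    @property
    def params(self) -> list[Tensor]:
        ps = list(self.gcn.params) + list(self.vae.params)
        if self.img is not None:
            ps += self.img.params
        if self.attention is not None:
            ps += self.attention.params
        return ps + self.decoder.params

    def forward(self, x1: Tensor, a_norm: Tensor | None, x2: Tensor | None,
                eps: np.ndarray | None):
        """One full forward pass; eps=None is eval mode.

        Returns (h1_list, h2_list, h3_list, mu, logvar, fused, alphas, x1_hat).
        """
        cfg = self.cfg
        if isinstance(self.gcn, GCNBranch):
            h1 = self.gcn.forward(x1, a_norm)
        else:
            h1 = self.gcn.forward(x1)
        h2, mu, logvar = self.vae.forward(x1, eps)
        h3 = self.img.forward(x2) if self.img is not None else None

        latents = [h1[-1], h2[-1]] + ([h3[-1]] if h3 is not None else [])
        if self.attention is not None:
            fused, alphas = self.attention(latents)
        else:
            fused = latents[-1]
            alphas = Tensor(np.ones((1, x1.shape[1])))
        x1_hat = self.decoder.forward(fused)
        return h1, h2, h3, mu, logvar, fused, alphas, x1_hat


def _alignment_terms(h1, h2, h3, graph: SpatialGraph | None, cfg: TrainConfig,
                     step_rng: np.random.Generator):
    """Global and local alignment loss Tensors for the current forward pass.

    Kernel Gram matrices are shared between the global and local terms.
    """
    layers = range(1, len(h2)) if cfg.use_deep_alignment else [len(h2) - 1]
    neighbors = None
    if cfg.use_spatial and graph is not None:
        neighbors = graph.neighbors
        n = neighbors.shape[0]
        limit = cfg.local_subsample
        if limit is None and n > _LOCAL_FULL_SUM_LIMIT:
            limit = _LOCAL_SUBSAMPLE
        if limit is not None and limit < n:
            rows = step_rng.choice(n, size=limit, replace=False)
            neighbors = neighbors[np.sort(rows)]
            local_scale = n / float(limit)
        else:
            local_scale = 1.0

    global_t = Tensor(0.0)
    local_t = Tensor(0.0)
    bws = cfg.mmd.kernel_bandwidths
    targets = [h for h in (h1, h3) if h is not None]
    gxx_cache: dict[int, Tensor] = {}  # source Gram shared across targets
    for other in targets:
        for l in layers:
            if l not in gxx_cache:
                gxx_cache[l] = kernel_gram(h2[l], h2[l], bws)
            gxx = gxx_cache[l]
            gxy = kernel_gram(h2[l], other[l], bws)
            gyy = kernel_gram(other[l], other[l], bws)
            global_t = global_t + mmd2_from_grams(gxx, gxy, gyy, cfg.mmd.estimator)
            if neighbors is not None:
                local_t = local_t + local_alignment_from_grams(
                    gxx, gxy, gyy, neighbors, cfg.mmd.estimator
                ) * local_scale
    return global_t, local_t


def fit(
    ds: SRTDataset,
    graph: SpatialGraph | None,
    X2: np.ndarray | None,
    cfg: TrainConfig,
) -> FitResult:
    """Train the model on a preprocessed (HVG + log1p) dataset.

    ``graph`` may be None only when ``cfg.use_spatial`` is False; ``X2`` is
    the raw image-feature matrix (standardized internally) or None for the
    image-free ablation.
    """
    if not ds.log_transformed:
        raise StmdaError("fit expects log1p-transformed expression")
    if cfg.use_spatial and graph is None:
        raise ParameterError("use_spatial=True requires a spatial graph")

    rng = np.random.default_rng(cfg.seed)
    x1 = Tensor(ds.expression)
    a_norm = None
    if cfg.use_spatial:
        a_norm = Tensor(np.asarray(graph.A_norm.todense()))
    x2 = None
    n_feat = None
    if X2 is None and cfg.use_image and ds.image_features is not None:
        X2 = ds.image_features
    if cfg.use_image and X2 is not None:
        X2s = standardize_features(X2)
        x2 = Tensor(X2s)
        n_feat = X2s.shape[0]

    model = _Model(ds.n_genes, n_feat, cfg, rng)
    optimizer = _Adam(model.params, lr=cfg.learning_rate)
    align_on = cfg.use_any_alignment and cfg.lambda_align > 0

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        eps = rng.standard_normal((cfg.latent_dim, ds.n_spots))
        h1, h2, h3, mu, logvar, fused, _, x1_hat = model.forward(
            x1, a_norm, x2, eps
        )
        n = float(ds.n_spots)
        diff = x1 - x1_hat
        recon_t = (diff * diff).sum() / n
        kl_t = ((mu * mu + logvar.exp() - logvar - 1.0).sum() * 0.5) / n
        if align_on:
            step_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, epoch])
            )
            global_t, local_t = _alignment_terms(h1, h2, h3, graph, cfg, step_rng)
            loss = recon_t + kl_t + cfg.lambda_align * (global_t + local_t)
        else:
            global_t = local_t = Tensor(0.0)
            loss = recon_t + kl_t

        record = {
            "epoch": epoch,
            "recon": recon_t.item(),
            "kl": kl_t.item(),
            "mmd_global": global_t.item(),
            "mmd_local": local_t.item(),
            "total": loss.item(),
        }
        for name in ("recon", "kl", "mmd_global", "mmd_local", "total"):
            if not np.isfinite(record[name]):
                raise StmdaError(
                    f"loss component {name!r} diverged at epoch {epoch}"
                )
        history.append(record)
        logger.debug(
            "epoch %d recon %.4f kl %.4f mmd_g %.4f mmd_l %.4f total %.4f",
            epoch, record["recon"], record["kl"], record["mmd_global"],
            record["mmd_local"], record["total"],
        )

        optimizer.zero_grad()
        loss.backward()
        optimizer.step()

    # eval-mode pass: latent = mu, no sampling
    h1, h2, h3, mu, logvar, fused, alphas, x1_hat = model.forward(
        x1, a_norm, x2, eps=None
    )
    stack = ModalityStack(
        H1=[t.data.copy() for t in h1],
        H2=[t.data.copy() for t in h2],
        H3=None if h3 is None else [t.data.copy() for t in h3],
        mu=mu.data.copy(),
        logvar=logvar.data.copy(),
        H=fused.data.copy(),
        alphas=alphas.data.copy(),
    )
    return FitResult(
        stack=stack,
        denoised=x1_hat.data.copy(),
        loss_history=history,
        config=cfg,
        seed=cfg.seed,
    )


def select_lambda(
    ds: SRTDataset,
    graph: SpatialGraph | None,
    X2: np.ndarray | None,
    candidates: list[float],
    criterion: str,
    reference_labels: np.ndarray,
    base_cfg: TrainConfig | None = None,
    n_neighbors: int = 15,
) -> float:
    """Grid-search lambda by clustering agreement with reference labels.

    Fits once per candidate (same seed), clusters the joint embedding to the
    number of reference classes, scores by ARI or purity, and returns the
    argmax; ties go to the smaller lambda.
    """
    if not candidates:
        raise ParameterError("candidate list is empty")
    if criterion not in ("ari_vs_reference", "purity_vs_reference"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    from .downstream import ari, cluster_embedding, purity

    reference_labels = np.asarray(reference_labels)
    n_classes = len(np.unique(reference_labels))
    base = base_cfg or TrainConfig()
    best_lambda, best_score = None, -np.inf
    for lam in sorted(candidates):
        cfg = replace(base, lambda_align=float(lam))
        result = fit(ds, graph, X2, cfg)
        domains = cluster_embedding(
            result.embedding, n_neighbors=n_neighbors,
            target_domains=n_classes, seed=cfg.seed,
        )
        if criterion == "ari_vs_reference":
            score = ari(domains.labels, reference_labels)
        else:
            score = purity(domains.labels, reference_labels)
        logger.info("lambda %.3g -> %s %.4f", lam, criterion, score)
        if score > best_score:
            best_lambda, best_score = float(lam), score
    return best_lambda
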