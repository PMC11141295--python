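"""Modality branches, attention fusion and decoder.

Three encoders produce layer-wise representations of the same N spots:

* a graph-convolutional branch over the normalized spatial adjacency
  (spatial-coordinates view of expression),
* a variational encoder of expression alone (Gaussian latent at the last
  layer, reparameterized sampling during training, mean in eval mode),
* a plain MLP over the per-spot image features.

All branches share the same layer widths (input -> 128 -> 10 by default)
but own their parameters — the branch inputs have different dimensions, so
weights cannot literally be shared.  A shared attention vector scores the
three final-layer representations per spot; the softmax-weighted sum is the
joint representation H, which a mirror-image decoder maps back to
expression space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat_rows, softmax_rows
from .exceptions import ShapeError

__all__ = [
    "BranchSpec",
    "DecoderSpec",
    "ModalityStack",
    "DenseLayer",
    "GCNBranch",
    "MLPBranch",
    "VAEBranch",
    "AttentionFusion",
    "Decoder",
    "glorot",
]


def glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


_ACTIVATIONS = {
    "elu": lambda t: t.elu(),
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
}


@dataclass
class BranchSpec:
    """Encoder architecture: widths from input to latent, activations.

    Hidden layers use ``activation``; the latent layer is linear so the
    alignment losses compare unconstrained representations.
    """

    layer_dims: list[int]
    activation: str = "elu"

    def __post_init__(self):
        if len(self.layer_dims) < 2:
            raise ShapeError("layer_dims needs at least input and latent widths")
        if self.activation not in _ACTIVATIONS:
            raise ShapeError(f"unknown activation {self.activation!r}")

    @property
    def n_layers(self) -> int:  # K
        return len(self.layer_dims) - 1

    @property
    def latent_dim(self) -> int:
        return self.layer_dims[-1]

    def layer_activation(self, layer: int) -> str:
        return self.activation if layer < self.n_layers else "identity"


@dataclass
class DecoderSpec:
    """Decoder architecture: widths from latent back to gene space."""

    layer_dims: list[int]
    activation: str = "elu"

    @classmethod
    def mirror(cls, branch: BranchSpec, output_dim: int) -> "DecoderSpec":
        return cls(list(reversed(branch.layer_dims[1:])) + [output_dim],
                   activation=branch.activation)

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims) - 1


@dataclass
class ModalityStack:
    """Per-layer representations of the three branches plus the fusion.

    ``H1``/``H2``/``H3`` are lists of layer outputs (numpy, eval mode) from
    layer 0 (the raw input) to layer K; missing branches are None.  ``H`` is
    the fused latent_dim x N joint representation and ``alphas`` the (3, N)
    per-spot attention weights over (spatial, expression, image).
    """

    H1: list[np.ndarray] | None
    H2: list[np.ndarray] | None
    H3: list[np.ndarray] | None
    mu: np.ndarray
    logvar: np.ndarray
    H: np.ndarray
    alphas: np.ndarray


class DenseLayer:
    def __init__(self, rng, fan_in: int, fan_out: int, activation: str):
        self.W = Tensor(glorot(rng, fan_out, fan_in), requires_grad=True)
        self.b = Tensor(np.zeros((fan_out, 1)), requires_grad=True)
        self.activation = activation

    def __call__(self, h: Tensor) -> Tensor:
        if h.shape[0] != self.W.shape[1]:
            raise ShapeError(
                f"layer expects {self.W.shape[1]} input rows, got {h.shape[0]}"
            )
        return _ACTIVATIONS[self.activation](self.W @ h + self.b)

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class MLPBranch:
    """Plain affine stack H^(l) = phi_l(W^(l) H^(l-1) + b^(l))."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers = [
            DenseLayer(rng, spec.layer_dims[l], spec.layer_dims[l + 1],
                       spec.layer_activation(l + 1))
            for l in range(spec.n_layers)
        ]

    def forward(self, x: Tensor) -> list[Tensor]:
        hs = [x]
        for layer in self.layers:
            hs.append(layer(hs[-1]))
        return hs

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]


class GCNBranch:
    """Graph-convolutional stack: each layer right-multiplies by the
    normalized adjacency, H^(l) = phi_l(W^(l) H^(l-1) A_norm + b^(l))."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers = [
            DenseLayer(rng, spec.layer_dims[l], spec.layer_dims[l + 1],
                       spec.layer_activation(l + 1))
            for l in range(spec.n_layers)
        ]

    def forward(self, x: Tensor, a_norm: Tensor) -> list[Tensor]:
        hs = [x]
        for layer in self.layers:
            h = hs[-1]
            if h.shape[0] != layer.W.shape[1]:
                raise ShapeError(
                    f"GCN layer expects {layer.W.shape[1]} rows, got {h.shape[0]}"
                )
            pre = (layer.W @ h) @ a_norm + layer.b
            hs.append(_ACTIVATIONS[layer.activation](pre))
        return hs

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]


class VAEBranch:
    """Variational encoder: deterministic layers to K-1, Gaussian heads at K.

    Training mode samples the latent via the reparameterization
    mu + sigma * eps with externally supplied eps; eval mode returns mu.
    """

    def __init__(self, spec: BranchSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers = [
            DenseLayer(rng, spec.layer_dims[l], spec.layer_dims[l + 1],
                       spec.layer_activation(l + 1))
            for l in range(spec.n_layers - 1)
        ]
        fan_in = spec.layer_dims[-2]
        self.W_mu = Tensor(glorot(rng, spec.latent_dim, fan_in), requires_grad=True)
        self.b_mu = Tensor(np.zeros((spec.latent_dim, 1)), requires_grad=True)
        self.W_logvar = Tensor(glorot(rng, spec.latent_dim, fan_in), requires_grad=True)
        self.b_logvar = Tensor(np.zeros((spec.latent_dim, 1)), requires_grad=True)

    def forward(
        self, x: Tensor, eps: np.ndarray | None = None
    ) -> tuple[list[Tensor], Tensor, Tensor]:
        """Return (layer list incl. latent, mu, logvar).

        ``eps`` standard-normal of latent shape enables the sampled latent;
        ``eps=None`` is eval mode (latent = mu).
        """
        hs = [x]
        for layer in self.layers:
            hs.append(layer(hs[-1]))
        pre = hs[-1]
        mu = self.W_mu @ pre + self.b_mu
        logvar = self.W_logvar @ pre + self.b_logvar
        if eps is None:
            z = mu
        else:
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        hs.append(z)
        return hs, mu, logvar

    @property
    def params(self) -> list[Tensor]:
        inner = [p for layer in self.layers for p in layer.params]
        return inner + [self.W_mu, self.b_mu, self.W_logvar, self.b_logvar]


class AttentionFusion:
    """Shared-vector attention over the three modality latents.

    Per spot i, modality m scores s_m = W_att^T tanh(W h_m + b); the softmax
    over the three scores weights the latent columns into the fused H.
    """

    def __init__(self, latent_dim: int, rng: np.random.Generator,
                 hidden_dim: int | None = None):
        d_prime = latent_dim if hidden_dim is None else hidden_dim
        self.W = Tensor(glorot(rng, d_prime, latent_dim), requires_grad=True)
        self.b = Tensor(np.zeros((d_prime, 1)), requires_grad=True)
        self.W_att = Tensor(glorot(rng, 1, d_prime), requires_grad=True)

    def __call__(self, latents: list[Tensor]) -> tuple[Tensor, Tensor]:
        """Fuse latent_dim x N latents; returns (H, alphas) with alphas
        shaped (n_modalities, N), each column on the probability simplex."""
        logits = concat_rows(
            [self.W_att @ (self.W @ h + self.b).tanh() for h in latents]
        )
        alphas = softmax_rows(logits)  # n_mod x N
        n_mod = len(latents)
        fused = None
        for m, h in enumerate(latents):
            selector = np.zeros((1, n_mod))
            selector[0, m] = 1.0
            row = Tensor(selector) @ alphas  # 1 x N
            weighted = h * row
            fused = weighted if fused is None else fused + weighted
        return fused, alphas

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b, self.W_att]


class Decoder:
    """Affine stack from the fused latent back to gene space; final layer
    linear, producing the mean of the reconstruction likelihood."""

    def __init__(self, spec: DecoderSpec, rng: np.random.Generator):
        self.spec = spec
        n = spec.n_layers
        self.layers = [
            DenseLayer(
                rng,
                spec.layer_dims[l],
                spec.layer_dims[l + 1],
                spec.activation if l + 1 < n else "identity",
            )
            for l in range(n)
        ]

    def forward(self, h: Tensor) -> Tensor:
        for layer in self.layers:
            h = layer(h)
        return h

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]
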