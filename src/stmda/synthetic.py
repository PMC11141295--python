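"""Self-contained synthetic SRT data with known spatial-domain labels.

The generator emulates the three modalities the model consumes: a lattice
of spots carved into contiguous domains (stripes, blobs or rings), counts
with domain-specific marker genes and multiplicative dropout, and per-spot
"image" feature vectors whose means track the domains.  Everything is
seeded, so fixtures are reproducible and need no downloads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SRTDataset, read_csv_bundle
from .exceptions import ParameterError

__all__ = ["SyntheticSpec", "generate", "write_fixture", "paint_domain_image"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic SRT generator.

    Defaults describe the stripe benchmark used throughout the test suite:
    a 30 x 30 lattice (900 spots) carved into 3 vertical stripe domains,
    100 genes of which 10 per domain are markers up-shifted by a factor
    e^1.5 ≈ 4.5 in their domain, Poisson counts with 30% dropout, and
    16-dim image features whose domain means are separated at twice the
    noise scale.
    """

    n_domains: int = 3
    layout: str = "stripes"  # stripes | blobs | rings
    grid: tuple[int, int] = (30, 30)
    n_genes: int = 100
    n_markers_per_domain: int = 10
    marker_log_effect: float = 1.5
    base_mean: float = 1.0
    dropout_rate: float = 0.3
    image_feature_dim: int = 16
    image_signal: float = 2.0
    noise: str = "poisson"  # poisson | nb
    nb_dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_domains < 2:
            raise ParameterError("n_domains must be >= 2")
        if self.n_markers_per_domain * self.n_domains > self.n_genes:
            raise ParameterError(
                "marker genes per domain x domains exceeds total genes"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.layout not in ("stripes", "blobs", "rings"):
            raise ParameterError(f"unknown layout {self.layout!r}")
        if self.noise not in ("poisson", "nb"):
            raise ParameterError(f"unknown noise model {self.noise!r}")


def _domain_labels(spec: SyntheticSpec, coords: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid
    x = coords[:, 0]
    if spec.layout == "stripes":
        edges = np.linspace(0, cols, spec.n_domains + 1)[1:-1]
        return np.searchsorted(edges, x, side="right").astype(np.int64)
    if spec.layout == "rings":
        center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
        r = np.linalg.norm(coords - center, axis=1)
        edges = np.quantile(r, np.linspace(0, 1, spec.n_domains + 1)[1:-1])
        return np.searchsorted(edges, r, side="right").astype(np.int64)
    # blobs: nearest of n_domains random centers
    centers = rng.uniform([0, 0], [cols - 1, rows - 1], size=(spec.n_domains, 2))
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).astype(np.int64)


def generate(spec: SyntheticSpec) -> tuple[SRTDataset, np.ndarray]:
    """Generate a dataset and its ground-truth domain labels.

    Counts for gene g at spot i are drawn from the noise model with mean
    ``base_mean * exp(marker_log_effect)`` if g is a marker of the spot's
    domain and ``base_mean`` otherwise, then zeroed independently with
    probability ``dropout_rate``.  Image features are the domain's mean
    vector (standard-normal entries) plus Gaussian noise with standard
    deviation ``1 / image_signal``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]).astype(np.float64)  # (x, y)
    n = rows * cols
    labels = _domain_labels(spec, coords, rng)

    log_means = np.full((spec.n_genes, n), np.log(spec.base_mean))
    for d in range(spec.n_domains):
        genes = slice(d * spec.n_markers_per_domain, (d + 1) * spec.n_markers_per_domain)
        log_means[genes, labels == d] += spec.marker_log_effect
    means = np.exp(log_means)

    if spec.noise == "poisson":
        counts = rng.poisson(means).astype(np.float64)
    else:  # negative binomial with mean mu and dispersion theta
        theta = spec.nb_dispersion
        shape = 1.0 / theta
        lam = rng.gamma(shape, means * theta)
        counts = rng.poisson(lam).astype(np.float64)
    if spec.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= spec.dropout_rate

    domain_means = rng.standard_normal((spec.n_domains, spec.image_feature_dim))
    noise_sd = 1.0 / spec.image_signal if spec.image_signal > 0 else 1e6
    image_features = (
        domain_means[labels].T
        + noise_sd * rng.standard_normal((spec.image_feature_dim, n))
    )

    ds = SRTDataset(
        expression=counts,
        gene_ids=[f"gene_{g}" for g in range(spec.n_genes)],
        spot_ids=[f"spot_{i}" for i in range(n)],
        coords=coords,
        image_features=image_features,
    )
    return ds, labels


def paint_domain_image(
    ds: SRTDataset, labels: np.ndarray, scale: int = 8, seed: int = 0
) -> SRTDataset:
    """Attach a painted raster (one flat color per domain plus speckle) and
    pixel coordinates to a synthetic dataset, to exercise tile extraction."""
    rng = np.random.default_rng(seed)
    coords = ds.coords
    x0, y0 = coords.min(axis=0)
    px = ((coords[:, 0] - x0) * scale + scale).astype(np.float64)
    py = ((coords[:, 1] - y0) * scale + scale).astype(np.float64)
    w = int(px.max()) + scale
    h = int(py.max()) + scale
    palette = rng.integers(40, 216, size=(int(labels.max()) + 1, 3))
    image = np.zeros((h, w, 3), dtype=np.uint8)
    half = scale // 2
    for (cx, cy), lab in zip(zip(px.astype(int), py.astype(int)), labels):
        image[max(cy - half, 0) : cy + half, max(cx - half, 0) : cx + half] = palette[lab]
    speckle = rng.integers(-10, 11, size=image.shape)
    image = np.clip(image.astype(int) + speckle, 0, 255).astype(np.uint8)
    from dataclasses import replace

    return replace(ds, image=image, pixel_coords=np.column_stack([px, py]))


def write_fixture(
    ds: SRTDataset, labels: np.ndarray, directory: str | os.PathLike
) -> list[str]:
    """Write the CSV bundle (expression, coords, features) plus true labels.

    The bundle round-trips through :func:`stmda.datasets.read_csv_bundle`.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    expr_path = out / "expression.csv"
    pd.DataFrame(
        ds.expression, index=pd.Index(ds.gene_ids, name="gene"), columns=ds.spot_ids
    ).to_csv(expr_path, float_format="%.10g")
    manifest.append(str(expr_path))

    coords_path = out / "coords.csv"
    pd.DataFrame(
        ds.coords, index=pd.Index(ds.spot_ids, name="spot_id"), columns=["x", "y"]
    ).to_csv(coords_path, float_format="%.10g")
    manifest.append(str(coords_path))

    if ds.image_features is not None:
        feat_path = out / "image_features.csv"
        pd.DataFrame(
            ds.image_features,
            index=pd.Index(
                [f"feature_{i}" for i in range(ds.image_features.shape[0])],
                name="feature",
            ),
            columns=ds.spot_ids,
        ).to_csv(feat_path, float_format="%.10g")
        manifest.append(str(feat_path))

    labels_path = out / "true_labels.csv"
    pd.DataFrame({"spot_id": ds.spot_ids, "domain": np.asarray(labels)}).to_csv(
        labels_path, index=False
    )
    manifest.append(str(labels_path))
    return manifest


def read_fixture(directory: str | os.PathLike) -> tuple[SRTDataset, np.ndarray]:
    """Read back a fixture written by :func:`write_fixture`."""
    d = Path(directory)
    features = d / "image_features.csv"
    ds = read_csv_bundle(
        d / "expression.csv",
        d / "coords.csv",
        features if features.exists() else None,
    )
    labels_df = pd.read_csv(d / "true_labels.csv").set_index("spot_id")
    labels = labels_df.loc[ds.spot_ids, "domain"].to_numpy()
    return ds, labels
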