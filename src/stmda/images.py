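"""Histology tile extraction and pluggable per-spot image embedding.

Feature extraction is pure: the embedder is applied once before training
and the resulting feature matrix X2 is a fixed input to the image branch.
Any object satisfying the :class:`Embedder` protocol (an ``output_dim``
attribute and a callable mapping a batch of tiles to a feature matrix) can
be plugged in; the built-in :class:`StatisticsEmbedder` computes
deterministic per-channel statistics and needs no pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .datasets import SRTDataset
from .exceptions import ModalityAbsentError, ParameterError

__all__ = [
    "SpotTileSet",
    "Embedder",
    "StatisticsEmbedder",
    "extract_tiles",
    "embed_tiles",
    "standardize_features",
]


@dataclass
class SpotTileSet:
    """Per-spot histology crops: N tiles of shape (side, side, 3)."""

    tiles: np.ndarray  # N x side x side x 3
    side: int

    @property
    def n_tiles(self) -> int:
        return self.tiles.shape[0]


@runtime_checkable
class Embedder(Protocol):
    """A deterministic map from tile batches to feature columns."""

    output_dim: int

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        """Map (batch, side, side, 3) tiles to an (output_dim, batch) matrix."""
        ...


class StatisticsEmbedder:
    """Hand-crafted 16-dim embedding: per-channel mean/SD + 10-bin histogram.

    Channels are scaled to [0, 1]; the grayscale intensity histogram is
    normalized to sum to 1 per tile.  Deterministic and training-free.
    """

    output_dim = 16

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles, dtype=np.float64) / 255.0
        if tiles.ndim != 4 or tiles.shape[-1] != 3:
            raise ParameterError("tiles must have shape (batch, side, side, 3)")
        means = tiles.mean(axis=(1, 2))  # batch x 3
        sds = tiles.std(axis=(1, 2))  # batch x 3
        gray = tiles.mean(axis=3)
        hists = np.stack(
            [
                np.histogram(g, bins=10, range=(0.0, 1.0))[0] / g.size
                for g in gray
            ]
        )
        return np.concatenate([means, sds, hists], axis=1).T  # 16 x batch


def extract_tiles(ds: SRTDataset, side: int = 32) -> SpotTileSet:
    """Crop a side x side tile centered on each spot's pixel position.

    Crops falling over the image border are zero-padded so every tile has
    the same shape.
    """
    if side <= 0:
        raise ParameterError(f"side must be positive, got {side}")
    if ds.image is None or ds.pixel_coords is None:
        raise ModalityAbsentError(
            "dataset has no image/pixel coordinates; run the image-free "
            "ablation (use_image=False) or supply precomputed image features"
        )
    image = np.asarray(ds.image)
    h, w = image.shape[:2]
    half = side // 2
    tiles = np.zeros((ds.n_spots, side, side, 3), dtype=image.dtype)
    for i, (px, py) in enumerate(ds.pixel_coords):
        # pixel_coords are (x, y) = (column, row)
        cx, cy = int(round(px)), int(round(py))
        x0, x1 = cx - half, cx - half + side
        y0, y1 = cy - half, cy - half + side
        sx0, sx1 = max(x0, 0), min(x1, w)
        sy0, sy1 = max(y0, 0), min(y1, h)
        if sx0 < sx1 and sy0 < sy1:
            tiles[i, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[
                sy0:sy1, sx0:sx1
            ]
    return SpotTileSet(tiles=tiles, side=side)


def embed_tiles(
    tiles: SpotTileSet, embedder: Embedder, batch_size: int = 256
) -> np.ndarray:
    """Embed all tiles into an (output_dim, N) feature matrix X2."""
    columns = []
    for start in range(0, tiles.n_tiles, batch_size):
        batch = tiles.tiles[start : start + batch_size]
        try:
            out = np.asarray(embedder(batch), dtype=np.float64)
        except Exception as exc:
            raise RuntimeError(
                f"embedder failed on tiles {start}..{start + len(batch) - 1}: {exc}"
            ) from exc
        if out.shape != (embedder.output_dim, len(batch)):
            raise ParameterError(
                f"embedder returned shape {out.shape}, expected "
                f"({embedder.output_dim}, {len(batch)})"
            )
        columns.append(out)
    features = np.concatenate(columns, axis=1)
    if not np.all(np.isfinite(features)):
        raise ParameterError("embedder produced non-finite features")
    return features


def standardize_features(X2: np.ndarray) -> np.ndarray:
    """Per-feature z-score across spots; zero-variance features map to 0.

    CNN-style features arrive on arbitrary scales; standardizing keeps the
    kernel-based alignment losses on a comparable footing across branches.
    """
    X2 = np.asarray(X2, dtype=np.float64)
    mu = X2.mean(axis=1, keepdims=True)
    sd = X2.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X2 - mu) / sd
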