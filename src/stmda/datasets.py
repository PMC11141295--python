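"""Core dataset container and readers/writers for standard SRT file layouts.

Expression is stored genes x spots (M x N).  All alignment between files is
done on spot identifiers, never on row order, so permuting a positions or
coordinates file changes nothing downstream.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import AlignmentError, FormatError, ParseError, StmdaError

logger = logging.getLogger(__name__)

__all__ = ["SRTDataset", "read_visium", "read_csv_bundle", "write_outputs"]


@dataclass
class SRTDataset:
    """A spatially resolved transcriptomics dataset.

    Attributes
    ----------
    expression:
        Genes x spots (M x N) matrix of non-negative reals.
    gene_ids, spot_ids:
        Row / column identifiers.
    coords:
        N x 2 spatial coordinates (x, y) in arbitrary but consistent units.
    pixel_coords:
        Optional N x 2 positions in the full-resolution image raster.
    image:
        Optional H x W x 3 uint8 histology raster.
    image_features:
        Optional F x N precomputed per-spot image feature matrix.
    log_transformed:
        Whether ``expression`` is log1p-transformed counts.
    """

    expression: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    pixel_coords: np.ndarray | None = None
    image: np.ndarray | None = None
    image_features: np.ndarray | None = None
    log_transformed: bool = False

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.gene_ids = list(map(str, self.gene_ids))
        self.spot_ids = list(map(str, self.spot_ids))
        m, n = self.expression.shape
        if len(self.gene_ids) != m:
            raise StmdaError(f"{len(self.gene_ids)} gene ids for {m} expression rows")
        if len(self.spot_ids) != n:
            raise StmdaError(f"{len(self.spot_ids)} spot ids for {n} expression columns")
        if len(set(self.spot_ids)) != n:
            raise StmdaError("spot ids are not unique")
        if self.coords.shape != (n, 2):
            raise StmdaError(f"coords shape {self.coords.shape} != ({n}, 2)")
        if np.any(self.expression < 0):
            raise StmdaError("expression has negative entries")
        if self.pixel_coords is not None:
            self.pixel_coords = np.asarray(self.pixel_coords, dtype=np.float64)
            if self.pixel_coords.shape != (n, 2):
                raise StmdaError("pixel_coords shape mismatch")
        if self.image_features is not None:
            self.image_features = np.asarray(self.image_features, dtype=np.float64)
            if self.image_features.shape[1] != n:
                raise StmdaError("image_features column count != number of spots")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_spots(self) -> int:
        return self.expression.shape[1]

    @property
    def expression_spots_by_genes(self) -> np.ndarray:
        """Spots x genes view for ecosystem (AnnData-style) interop."""
        return self.expression.T

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (spots x genes)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.expression.T.copy(),
            obs=pd.DataFrame(index=self.spot_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obsm["spatial"] = self.coords.copy()
        return adata

    def subset_genes(self, mask_or_idx) -> "SRTDataset":
        return replace(
            self,
            expression=self.expression[mask_or_idx],
            gene_ids=[self.gene_ids[i] for i in np.arange(self.n_genes)[mask_or_idx]],
        )

    def drop_empty_spots(self) -> "SRTDataset":
        """Remove spots with zero total counts (they would break the graph
        normalization, which divides by neighbor similarity sums)."""
        totals = self.expression.sum(axis=0)
        keep = totals > 0
        n_drop = int((~keep).sum())
        if n_drop == 0:
            return self
        logger.info("dropping %d spots with zero total counts", n_drop)
        idx = np.flatnonzero(keep)
        return replace(
            self,
            expression=self.expression[:, idx],
            spot_ids=[self.spot_ids[i] for i in idx],
            coords=self.coords[idx],
            pixel_coords=None if self.pixel_coords is None else self.pixel_coords[idx],
            image_features=None
            if self.image_features is None
            else self.image_features[:, idx],
        )


# --------------------------------------------------------------------------- IO


def _find_one(directory: Path, names: list[str], label: str) -> Path:
    for name in names:
        for candidate in (directory / name, directory / "spatial" / name):
            if candidate.exists():
                return candidate
    raise FormatError(f"missing {label} in {directory} (looked for {names})")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _read_positions(path: Path) -> pd.DataFrame:
    """Read either Space Ranger positions dialect (with or without header)."""
    head = pd.read_csv(path, nrows=1, header=None)
    has_header = str(head.iloc[0, 0]).strip().lower() == "barcode"
    if has_header:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
    else:
        df = pd.read_csv(path, header=None, names=_POSITION_COLUMNS)
    missing = [c for c in _POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"positions file {path} lacks columns {missing}")
    return df


def read_visium(path: str | os.PathLike) -> SRTDataset:
    """Read a 10x-Genomics-style output directory.

    Expects an MTX triplet (``matrix.mtx[.gz]``, features/genes, barcodes)
    plus a ``tissue_positions(.csv|_list.csv)`` file; spots are restricted to
    in-tissue barcodes and aligned to the matrix barcode order.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    mtx = _find_one(directory, ["matrix.mtx", "matrix.mtx.gz"], "matrix.mtx")
    feats = _find_one(
        directory,
        ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"],
        "features.tsv",
    )
    barcodes = _find_one(directory, ["barcodes.tsv", "barcodes.tsv.gz"], "barcodes.tsv")
    positions = _find_one(
        directory,
        [
            "tissue_positions.csv",
            "tissue_positions_list.csv",
            "tissue_positions.csv.gz",
            "tissue_positions_list.csv.gz",
        ],
        "tissue positions",
    )

    matrix = sp.csc_matrix(scipy.io.mmread(str(mtx)))  # genes x spots
    gene_ids = [line.split("\t")[0] for line in _read_lines(feats)]
    spot_ids = _read_lines(barcodes)
    if matrix.shape != (len(gene_ids), len(spot_ids)):
        raise FormatError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(gene_ids)} features x {len(spot_ids)} barcodes"
        )

    pos = _read_positions(positions)
    pos = pos[pos["in_tissue"].astype(int) == 1]
    pos = pos.set_index(pos["barcode"].astype(str))

    in_tissue = [b for b in spot_ids if b in pos.index]
    unmatched = int(pos.shape[0] - len(set(in_tissue)))
    if unmatched > 0:
        raise AlignmentError(
            f"{unmatched} in-tissue barcode(s) in the positions file are absent "
            "from the matrix"
        )
    col_of = {b: i for i, b in enumerate(spot_ids)}
    cols = [col_of[b] for b in in_tissue]
    expr = np.asarray(matrix[:, cols].todense(), dtype=np.float64)
    sub = pos.loc[in_tissue]
    coords = sub[["array_row", "array_col"]].to_numpy(dtype=np.float64)
    pixel_coords = sub[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(
        dtype=np.float64
    )

    image = None
    for name in ("image.png", "image.tiff", "tissue_hires_image.png"):
        candidate = directory / name
        if not candidate.exists():
            candidate = directory / "spatial" / name
        if candidate.exists():
            from PIL import Image

            image = np.asarray(Image.open(candidate).convert("RGB"))
            break

    ds = SRTDataset(
        expression=expr,
        gene_ids=gene_ids,
        spot_ids=in_tissue,
        coords=coords,
        pixel_coords=pixel_coords,
        image=image,
    )
    return ds.drop_empty_spots()


def _read_numeric_table(path: str | os.PathLike, index_col: int = 0) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=index_col)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ParseError(f"non-numeric value in {path} at row {row!r}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise ParseError(f"missing values in {path}")
    return df


def read_csv_bundle(
    expr: str | os.PathLike,
    coords: str | os.PathLike,
    features: str | os.PathLike | None = None,
) -> SRTDataset:
    """Read a dense CSV bundle: genes x spots expression, spot coordinates,
    optional per-spot feature matrix.  Coordinate rows are joined on spot id,
    so their order is irrelevant."""
    raw_header = pd.read_csv(expr, header=None, nrows=1).iloc[0, 1:].astype(str)
    if raw_header.duplicated().any():
        raise FormatError(f"duplicate spot ids in {expr}")
    expr_df = _read_numeric_table(expr)
    spot_ids = [str(c) for c in expr_df.columns]

    coords_df = pd.read_csv(coords, index_col=0)
    coords_df.index = coords_df.index.map(str)
    if coords_df.index.has_duplicates:
        raise FormatError(f"duplicate spot ids in {coords}")
    missing = [s for s in spot_ids if s not in coords_df.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} spot id(s) in the expression file have no coordinates"
        )
    coords_arr = coords_df.loc[spot_ids].iloc[:, :2].to_numpy(dtype=np.float64)

    image_features = None
    if features is not None:
        feat_df = _read_numeric_table(features)
        feat_cols = [str(c) for c in feat_df.columns]
        missing = [s for s in spot_ids if s not in feat_cols]
        if missing:
            raise AlignmentError(
                f"{len(missing)} spot id(s) missing from the feature file"
            )
        image_features = feat_df[spot_ids].to_numpy(dtype=np.float64)

    ds = SRTDataset(
        expression=expr_df.to_numpy(dtype=np.float64),
        gene_ids=[str(g) for g in expr_df.index],
        spot_ids=spot_ids,
        coords=coords_arr,
        image_features=image_features,
    )
    return ds.drop_empty_spots()


def write_outputs(result, outdir: str | os.PathLike) -> list[str]:
    """Write a :class:`~stmda.downstream.DomainResult` to ``outdir``.

    Writes domain labels and the joint embedding as CSV and the denoised
    expression as an MTX triplet; returns the list of written paths.
    """
    if not str(outdir):
        raise OSError("empty output directory path")
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    manifest: list[str] = []
    labels_path = out / "domains.csv"
    pd.DataFrame({"spot_id": result.spot_ids, "domain": result.labels}).to_csv(
        labels_path, index=False
    )
    manifest.append(str(labels_path))

    emb = result.embedding  # latent_dim x N
    emb_df = pd.DataFrame(
        emb.T,
        index=pd.Index(result.spot_ids, name="spot_id"),
        columns=[f"latent_{i}" for i in range(emb.shape[0])],
    )
    emb_path = out / "embedding.csv"
    emb_df.to_csv(emb_path, float_format="%.10g")
    manifest.append(str(emb_path))

    denoised_path = out / "denoised.mtx"
    scipy.io.mmwrite(str(denoised_path), sp.coo_matrix(result.denoised))
    manifest.append(str(denoised_path))
    genes_path = out / "denoised_genes.tsv"
    genes_path.write_text("\n".join(result.gene_ids) + "\n")
    manifest.append(str(genes_path))
    spots_path = out / "denoised_spots.tsv"
    spots_path.write_text("\n".join(result.spot_ids) + "\n")
    manifest.append(str(spots_path))
    return manifest
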