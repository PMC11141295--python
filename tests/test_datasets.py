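"""Dataset container invariants and file round trips."""

import gzip

import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse as sp

from stmda.datasets import SRTDataset, read_csv_bundle, read_visium, write_outputs
from stmda.downstream import DomainResult
from stmda.exceptions import AlignmentError, FormatError, ParseError, StmdaError
from stmda.synthetic import SyntheticSpec, generate, write_fixture, read_fixture


def _write_visium(directory, expr, gene_ids, barcodes, positions_rows, gz=False):
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(expr))
    if gz:
        raw = (directory / "matrix.mtx").read_bytes()
        (directory / "matrix.mtx").unlink()
        with gzip.open(directory / "matrix.mtx.gz", "wb") as fh:
            fh.write(raw)
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in gene_ids)
    )
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))
    header = "barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,pxl_col_in_fullres\n"
    (directory / "tissue_positions.csv").write_text(
        header + "".join(",".join(map(str, row)) + "\n" for row in positions_rows)
    )


@pytest.fixture
def visium_dir(tmp_path, tiny_dataset):
    ds = tiny_dataset
    rows = [
        (s, 1, int(ds.coords[i, 0]), int(ds.coords[i, 1]), 10 * i, 20 * i)
        for i, s in enumerate(ds.spot_ids)
    ]
    _write_visium(tmp_path / "visium", ds.expression, ds.gene_ids, ds.spot_ids, rows)
    return tmp_path / "visium"


class TestReadVisium:
    def test_round_trip_identity(self, visium_dir, tiny_dataset):
        ds = read_visium(visium_dir)
        np.testing.assert_array_equal(ds.expression, tiny_dataset.expression)
        assert ds.spot_ids == tiny_dataset.spot_ids
        assert ds.gene_ids == tiny_dataset.gene_ids
        # coords from array positions, pixel coords from pxl columns (x=col)
        np.testing.assert_array_equal(ds.pixel_coords[:, 0], [0, 20, 40, 60])

    def test_missing_file_is_named(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FormatError, match="matrix.mtx"):
            read_visium(tmp_path / "empty")

    def test_unmatched_barcode_counted(self, tmp_path, tiny_dataset):
        ds = tiny_dataset
        rows = [
            (s, 1, int(ds.coords[i, 0]), int(ds.coords[i, 1]), 0, 0)
            for i, s in enumerate(ds.spot_ids)
        ] + [("GHOST", 1, 9, 9, 0, 0)]
        _write_visium(tmp_path / "v", ds.expression, ds.gene_ids, ds.spot_ids, rows)
        with pytest.raises(AlignmentError, match="1 "):
            read_visium(tmp_path / "v")

    def test_explicit_zero_matches_dense_reader(self, tmp_path, tiny_dataset):
        ds = tiny_dataset
        coo = sp.coo_matrix(ds.expression)
        # append an explicit stored zero entry
        row = np.append(coo.row, 0)
        col = np.append(coo.col, 1)
        data = np.append(coo.data, 0.0)
        explicit = sp.coo_matrix((data, (row, col)), shape=ds.expression.shape)
        d = tmp_path / "vz"
        d.mkdir()
        scipy.io.mmwrite(str(d / "matrix.mtx"), explicit)
        (d / "features.tsv").write_text("".join(g + "\n" for g in ds.gene_ids))
        (d / "barcodes.tsv").write_text("".join(b + "\n" for b in ds.spot_ids))
        header = "barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,pxl_col_in_fullres\n"
        (d / "tissue_positions.csv").write_text(
            header
            + "".join(
                f"{s},1,{int(ds.coords[i,0])},{int(ds.coords[i,1])},0,0\n"
                for i, s in enumerate(ds.spot_ids)
            )
        )
        from_mtx = read_visium(d)
        bundle_dir = tmp_path / "bundle"
        write_fixture(ds, np.zeros(ds.n_spots, dtype=int), bundle_dir)
        from_dense = read_csv_bundle(
            bundle_dir / "expression.csv", bundle_dir / "coords.csv"
        )
        np.testing.assert_allclose(from_mtx.expression, from_dense.expression)

    def test_out_of_tissue_spots_excluded(self, tmp_path, tiny_dataset):
        ds = tiny_dataset
        rows = [
            (s, 1 if i != 2 else 0, int(ds.coords[i, 0]), int(ds.coords[i, 1]), 0, 0)
            for i, s in enumerate(ds.spot_ids)
        ]
        _write_visium(tmp_path / "v", ds.expression, ds.gene_ids, ds.spot_ids, rows)
        out = read_visium(tmp_path / "v")
        assert out.n_spots == 3
        assert "s2" not in out.spot_ids


class TestReadCsvBundle:
    def test_small_bundle_shapes(self, tmp_path):
        (tmp_path / "expr.csv").write_text("gene,a,b\ng1,1,2\ng2,3,4\ng3,5,6\n")
        (tmp_path / "coords.csv").write_text("spot,x,y\na,0,0\nb,1,0\n")
        ds = read_csv_bundle(tmp_path / "expr.csv", tmp_path / "coords.csv")
        assert ds.n_genes == 3 and ds.n_spots == 2

    def test_coords_order_invariance(self, tmp_path):
        (tmp_path / "expr.csv").write_text("gene,a,b\ng1,1,2\ng2,3,4\n")
        (tmp_path / "c1.csv").write_text("spot,x,y\na,0,0\nb,1,0\n")
        (tmp_path / "c2.csv").write_text("spot,x,y\nb,1,0\na,0,0\n")
        d1 = read_csv_bundle(tmp_path / "expr.csv", tmp_path / "c1.csv")
        d2 = read_csv_bundle(tmp_path / "expr.csv", tmp_path / "c2.csv")
        np.testing.assert_array_equal(d1.coords, d2.coords)
        np.testing.assert_array_equal(d1.expression, d2.expression)

    def test_feature_file_populates_image_features(self, tmp_path):
        (tmp_path / "expr.csv").write_text("gene,a,b\ng1,1,2\n")
        (tmp_path / "coords.csv").write_text("spot,x,y\na,0,0\nb,1,0\n")
        feats = "feat," + "a,b\n" + "".join(f"f{i},{i},{i+1}\n" for i in range(5))
        (tmp_path / "feats.csv").write_text(feats)
        ds = read_csv_bundle(
            tmp_path / "expr.csv", tmp_path / "coords.csv", tmp_path / "feats.csv"
        )
        assert ds.image_features.shape == (5, 2)

    def test_duplicate_spot_ids_raise(self, tmp_path):
        (tmp_path / "expr.csv").write_text("gene,a,a\ng1,1,2\n")
        (tmp_path / "coords.csv").write_text("spot,x,y\na,0,0\n")
        with pytest.raises(FormatError):
            read_csv_bundle(tmp_path / "expr.csv", tmp_path / "coords.csv")

    def test_non_numeric_cell_names_location(self, tmp_path):
        (tmp_path / "expr.csv").write_text("gene,a,b\ng1,1,oops\ng2,3,4\n")
        (tmp_path / "coords.csv").write_text("spot,x,y\na,0,0\nb,1,0\n")
        with pytest.raises(ParseError, match="g1"):
            read_csv_bundle(tmp_path / "expr.csv", tmp_path / "coords.csv")


class TestWriteOutputs:
    def _result(self, n=4):
        return DomainResult(
            labels=np.array([0, 1, 0, 1][:n]),
            embedding=np.arange(10 * n, dtype=float).reshape(10, n) / 7,
            denoised=np.arange(3 * n, dtype=float).reshape(3, n),
            resolution_used=1.0,
            spot_ids=[f"s{i}" for i in range(n)],
            gene_ids=["g0", "g1", "g2"],
        )

    def test_labels_row_count(self, tmp_path):
        manifest = write_outputs(self._result(), tmp_path / "out")
        labels = pd.read_csv(tmp_path / "out" / "domains.csv")
        assert len(labels) == 4
        assert len(manifest) >= 3

    def test_embedding_text_round_trip(self, tmp_path):
        result = self._result()
        write_outputs(result, tmp_path / "out")
        emb = pd.read_csv(tmp_path / "out" / "embedding.csv", index_col=0)
        np.testing.assert_allclose(emb.to_numpy().T, result.embedding, atol=1e-6)

    def test_empty_outdir_raises(self):
        with pytest.raises(OSError):
            write_outputs(self._result(), "")


class TestContainer:
    def test_rejects_negative_expression(self):
        with pytest.raises(StmdaError):
            SRTDataset(
                expression=np.array([[-1.0]]),
                gene_ids=["g"],
                spot_ids=["s"],
                coords=np.zeros((1, 2)),
            )

    def test_rejects_duplicate_spot_ids(self):
        with pytest.raises(StmdaError):
            SRTDataset(
                expression=np.ones((1, 2)),
                gene_ids=["g"],
                spot_ids=["s", "s"],
                coords=np.zeros((2, 2)),
            )

    def test_drop_empty_spots(self, tiny_dataset):
        expr = tiny_dataset.expression.copy()
        expr[:, 1] = 0
        import dataclasses

        ds = dataclasses.replace(tiny_dataset, expression=expr)
        out = ds.drop_empty_spots()
        assert out.n_spots == 3 and "s1" not in out.spot_ids


def test_fixture_write_read_round_trip(tmp_path):
    spec = SyntheticSpec(grid=(4, 5), n_genes=12, n_markers_per_domain=2, seed=3)
    ds, labels = generate(spec)
    manifest = write_fixture(ds, labels, tmp_path / "fx")
    assert len(manifest) >= 3
    back, labels_back = read_fixture(tmp_path / "fx")
    np.testing.assert_allclose(back.expression, ds.expression, rtol=1e-6)
    np.testing.assert_array_equal(labels_back, labels)
    np.testing.assert_allclose(back.image_features, ds.image_features, rtol=1e-6)
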