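import numpy as np
import pytest

from stmda.datasets import SRTDataset
from stmda.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """6 genes x 4 spots with simple counts and a 2x2 grid."""
    expr = np.array(
        [
            [5, 0, 1, 2],
            [0, 3, 0, 1],
            [2, 2, 2, 2],
            [0, 0, 4, 4],
            [1, 1, 0, 0],
            [3, 1, 2, 0],
        ],
        dtype=float,
    )
    coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    return SRTDataset(
        expression=expr,
        gene_ids=[f"g{i}" for i in range(6)],
        spot_ids=[f"s{i}" for i in range(4)],
        coords=coords,
    )


@pytest.fixture
def small_labeled_dataset():
    """A quick 3-domain stripes dataset for optimization sanity checks."""
    spec = SyntheticSpec(grid=(10, 10), n_genes=60, n_markers_per_domain=5, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def flagship():
    """The stripe benchmark: 30x30 grid, 100 genes, dropout 0.3, seed 0."""
    spec = SyntheticSpec()
    ds, labels = generate(spec)
    return ds, labels, spec


@pytest.fixture(scope="session")
def flagship_fit(flagship):
    """One full-pipeline fit (lambda=1, 300 epochs) on the stripe benchmark,
    shared by the recovery and denoising tests."""
    from stmda.graph import build_spatial_graph
    from stmda.preprocessing import compute_pca, log1p_transform
    from stmda.training import TrainConfig, fit

    ds, labels, _ = flagship
    lds = log1p_transform(ds)
    graph = build_spatial_graph(lds.coords, compute_pca(lds, 15), k=6)
    result = fit(lds, graph, None, TrainConfig(epochs=300, seed=0))
    return lds, labels, graph, result
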