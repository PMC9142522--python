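import numpy as np
import pytest

from debleed.containers import SlideCounts, SpotGeometry


@pytest.fixture
def line_geometry() -> SpotGeometry:
    """Five collinear spots, 100 px apart: three tissue then two background."""
    return SpotGeometry(
        barcode=np.array([f"s{i}" for i in range(5)], dtype=object),
        pixel_row=np.zeros(5),
        pixel_col=np.arange(5) * 100.0,
        array_row=np.zeros(5, dtype=int),
        array_col=np.arange(5),
        in_tissue=np.array([1, 1, 1, 0, 0], dtype=bool),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_instance(seed: int, n_genes: int = 3, n_rows: int = 3,
                    n_cols: int = 4, tissue_fraction: float = 0.5):
    """Small random slide + geometry for property tests."""
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    rows, cols = np.divmod(np.arange(n), n_cols)
    n_t = max(1, int(n * tissue_fraction))
    in_tissue = np.zeros(n, dtype=bool)
    in_tissue[:n_t] = True
    geometry = SpotGeometry(
        barcode=np.array([f"b{i:03d}" for i in range(n)], dtype=object),
        pixel_row=rows * 100.0,
        pixel_col=cols * 100.0,
        array_row=rows,
        array_col=cols,
        in_tissue=in_tissue,
    )
    counts = rng.poisson(rng.uniform(0.5, 30.0, size=(n_genes, 1)), size=(n_genes, n))
    return SlideCounts(
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        counts=counts,
    ), geometry
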