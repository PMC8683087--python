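import numpy as np
import pytest
import scipy.sparse as sp

from urchin_atlas import CountMatrix, SimConfig, simulate_atlas


def make_matrix(arr, genes=None, cells=None) -> CountMatrix:
    """Small dense-array helper for hand-crafted count matrices."""
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"cell{j}" for j in range(arr.shape[1])]
    return CountMatrix(sp.csr_matrix(arr), genes, cells)


@pytest.fixture(scope="session")
def small_atlas():
    """A 6-cluster atlas with planted markers and a planted panel subcluster."""
    cfg = SimConfig(
        n_clusters=6,
        cells_per_cluster=80,
        n_genes=400,
        markers_per_cluster=3,
        marker_log2fc=3.0,
        panel_size=12,
        panel_cluster="c6",
        n_subclusters=3,
        seed=42,
    )
    return simulate_atlas(cfg)
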