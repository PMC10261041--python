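import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from skinmap import sc_core, synthgen


@pytest.fixture(scope="session")
def small_sim():
    """A 400-cell default-config tissue with all blocks present."""
    cfg = synthgen.default_config(seed=1, n_cells=400)
    cells, truth = synthgen.simulate_cells(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def atlas6():
    """A 2,000-cell six-type atlas for recovery benchmarks."""
    cfg = synthgen.atlas_config(seed=3, n_cells=2000)
    cells, truth = synthgen.simulate_cells(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def atlas6_nm(atlas6):
    _, cells, truth = atlas6
    filtered, _ = sc_core.qc_filter(cells)
    nm = sc_core.normalize_cp10k_log(filtered)
    return nm, truth


def make_adata(counts, gene_names=None, obs=None):
    counts = np.asarray(counts)
    n_obs, n_var = counts.shape
    genes = gene_names or [f"g{i}" for i in range(n_var)]
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(n_obs)])
    return ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.float64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


@pytest.fixture
def toy_adata():
    """Deterministic 6-cell x 8-gene toy matrix."""
    rng = np.random.default_rng(0)
    return make_adata(rng.integers(0, 20, size=(6, 8)))
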