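import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import atriakit as ak

# the generators deliberately warn about degenerate slices in small fixtures
warnings.filterwarnings("ignore", category=UserWarning)


def make_adata(counts: np.ndarray, genes=None, cells=None, **kwargs) -> ad.AnnData:
    """Plain AnnData around a dense count array (test helper)."""
    n, g = counts.shape
    return ad.AnnData(
        X=np.asarray(counts, dtype=float),
        obs=pd.DataFrame(index=cells or [f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=genes or [f"G{j:05d}" for j in range(g)]),
        **kwargs,
    )


@pytest.fixture(scope="session")
def droplet_sim():
    """One simulated droplet dataset shared by the QC tests."""
    cfg = ak.DropletSimConfig(n_droplets=2000, seed=0)
    adata, truth = ak.generate_droplet_dataset(cfg)
    return adata, truth, ak.droplet_gene_sets(adata)


@pytest.fixture(scope="session")
def module_sim_counts():
    """Planted-module count matrix (4 x 20-gene modules, loading 0.8)."""
    cfg = ak.ModuleSimConfig(
        n_cells=5000, n_genes=200, module_sizes=(20, 20, 20, 20),
        loading=0.8, mode="counts", seed=0,
    )
    x, truth = ak.generate_module_dataset(cfg)
    return x, truth
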