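import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from crossorg import SimConfig, generate_study, normalize


@pytest.fixture(scope="session")
def small_config():
    """Desk-size paired simulation used by several module tests."""
    return SimConfig(
        n_genes=600,
        cell_types=(("Neurons", 120), ("Astrocytes", 80), ("Other", 60)),
        n_shared=20, n_contrasting=20, n_specific_A=10, n_specific_B=10,
        seed=1234,
    )


@pytest.fixture(scope="session")
def study_pair(small_config):
    A, truth = generate_study(small_config, "A")
    B, _ = generate_study(small_config, "B")
    return A, B, truth


@pytest.fixture(scope="session")
def recovery_pair():
    """Spec-scale single-cell-type pair: 300 cells/group, planted 40/40/20/20."""
    cfg = SimConfig(cell_types=(("Neurons", 300),), seed=20240)
    A, truth = generate_study(cfg, "A")
    B, _ = generate_study(cfg, "B")
    return normalize(A), normalize(B), truth


def make_adata(counts, condition=None, cell_type=None, genes=None):
    """Small dense AnnData helper for hand-built examples."""
    X = np.asarray(counts)
    n, m = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    if condition is not None:
        obs["condition"] = list(condition)
    if cell_type is not None:
        obs["cell_type"] = list(cell_type)
    var = pd.DataFrame(index=pd.Index(genes or [f"g{j}" for j in range(m)], name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    return ad.AnnData(X=sparse.csr_matrix(X.astype(float)), obs=obs, var=var)
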