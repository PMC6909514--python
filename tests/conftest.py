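import numpy as np
import pytest
import scipy.sparse as sp

from scdemux import (
    AlleleCountData,
    FitConfig,
    SimConfig,
    VariantTable,
    filter_variants,
    simulate_pool,
)


def make_data(A, D, cells=None, chrom="1"):
    """AlleleCountData from dense arrays, with auto-generated metadata."""
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    n, m = D.shape
    if cells is None:
        cells = [f"C{j}" for j in range(m)]
    variants = VariantTable.from_arrays(
        chrom=[chrom] * n,
        pos=np.arange(1, n + 1),
        ref=["A"] * n,
        alt=["G"] * n,
    )
    return AlleleCountData(sp.csr_matrix(A), sp.csr_matrix(D), cells, variants)


@pytest.fixture(scope="session")
def small_pool():
    """A modest 4-donor pool with doublets: enough signal for recovery
    tests while keeping the suite fast."""
    cfg = SimConfig(
        n_donors=4, cells_per_donor=150, n_variants=800, doublet_rate=0.08, seed=11
    )
    data, truth = simulate_pool(cfg)
    return filter_variants(data), truth, cfg


@pytest.fixture(scope="session")
def small_fit(small_pool):
    from scdemux import fit

    data, truth, _ = small_pool
    config = FitConfig(n_init=10, warmup_iters=10, seed=7)
    return fit(data, 4, config=config), data, truth
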