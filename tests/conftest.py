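import numpy as np
import pytest

import mbimpute as mb


@pytest.fixture(scope="session")
def all_sources_ds():
    """Seeded all-sources synthetic dataset (n=50, m=60) with injected
    non-biological zeros and known truth mask."""
    return mb.simulate(mb.SimulationConfig(scheme="all", seed=7))


@pytest.fixture(scope="session")
def all_sources_run(all_sources_ds):
    """Full two-step run (detection + CV-fitted imputation) on the
    all-sources dataset; shared because the CV fit is the slow part."""
    ds = all_sources_ds
    return mb.impute_abundance(ds.Y_observed, ds.X, ds.D, seed=1)


@pytest.fixture
def tiny_problem():
    """Small dense instance (n=6, m=5, k=2, q=1) for solver-level checks."""
    rng = np.random.default_rng(42)
    n, m = 6, 5
    Y = mb.AbundanceMatrix(
        rng.uniform(1.0, 5.0, size=(n, m)),
        [f"s{i}" for i in range(n)],
        [f"t{j}" for j in range(m)],
    )
    X = mb.CovariateMatrix(np.ones((n, 1)), ["intercept"])
    Dv = rng.uniform(1.0, 6.0, size=(m, m))
    Dv = (Dv + Dv.T) / 2
    np.fill_diagonal(Dv, 0.0)
    D = mb.PhyloDistanceMatrix(Dv, Y.taxon_ids)
    flags = np.zeros((n, m), dtype=bool)
    flags[rng.random((n, m)) < 0.2] = True
    flags[:2, :] = False  # keep |Omega| comfortably above 24
    mask = mb.MissingMask(flags, 0.5)
    neighbors = mb.select_neighbor_taxa(D, 2)
    return Y, X, D, mask, neighbors
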