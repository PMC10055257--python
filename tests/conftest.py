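import numpy as np
import pandas as pd
import pytest

from scqtl import synthdata as sd


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SimConfig(seed=7, n_donors=60, n_genes=12, snps_per_gene=10)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """Genotypes, kinship, design and cells for a 60-donor toy cohort."""
    G, K = sd.simulate_genotypes(small_cfg)
    design = sd.random_design(
        G, small_cfg, {"global": 2, "unique": 2, "interaction_only": 2}
    )
    adata = sd.simulate_cells(G, K, design, small_cfg)
    return G, K, design, adata


def make_stats(Bhat, S, conditions=None):
    from scqtl.mash import MultiConditionStats

    n, R = Bhat.shape
    conds = conditions or [f"ct{r}" for r in range(R)]
    ids = pd.Index([f"g{i:05d}:v{i:05d}" for i in range(n)])
    return MultiConditionStats(ids=ids, Bhat=Bhat, S=S, conditions=conds)
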