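import numpy as np
import pandas as pd
import pytest

import toxtempo as tt


def small_config(**overrides) -> tt.SimConfig:
    """A fast desk-scale study configuration shared across tests."""
    base = dict(
        n_genes=300,
        n_steatotic_compounds=3,
        n_negative_controls=1,
        n_response_genes=60,
        n_confounder_genes=20,
        n_gene_sets=10,
        set_size_range=(5, 15),
        n_compound_clusters=2,
        seed=11,
    )
    base.update(overrides)
    return tt.SimConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """One generated study reused by read-only tests."""
    cfg = small_config()
    study, truth, collection = tt.generate_study(cfg)
    return cfg, study, truth, collection


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
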