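import numpy as np
import pytest

from pancog import (
    SimulationParams,
    simulate_dataset,
)
from pancog.clustering import classify_families, mcl_cluster
from pancog.homology import build_similarity_graph


@pytest.fixture(scope="session")
def small_dataset():
    """Six strains, 60 root families, moderate gain/loss, 10% HGT genes."""
    params = SimulationParams(n_genomes=6, n_core_root=60, gain_rate=2.0,
                              loss_rate=0.3, subst_rate=0.02,
                              mean_protein_len=150, hgt_fraction=0.10, seed=11)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def small_graph(small_dataset):
    proteomes, _ = small_dataset
    return build_similarity_graph(proteomes)


@pytest.fixture(scope="session")
def small_families(small_dataset, small_graph):
    proteomes, _ = small_dataset
    return classify_families(mcl_cluster(small_graph), proteomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
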