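import numpy as np
import pandas as pd
import pytest

from chassiskit.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down study: full design (6 hosts, triplicates), fewer clusters."""
    return SimConfig(n_clusters=400, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_cluster_matrix(n_core, n_multi, n_unique, n_genomes=6, seed=0):
    """Gene-cluster matrix with an exact frequency-group composition."""
    rng = np.random.default_rng(seed)
    n = n_core + n_multi + n_unique
    occ = np.zeros((n, n_genomes), dtype=int)
    occ[:n_core] = 1
    for i in range(n_core, n_core + n_multi):
        size = rng.integers(2, n_genomes)
        occ[i, rng.choice(n_genomes, size=size, replace=False)] = 1
    for i in range(n_core + n_multi, n):
        occ[i, rng.integers(0, n_genomes)] = 1
    return pd.DataFrame(
        occ,
        index=[f"GC_{i:05d}" for i in range(n)],
        columns=[f"host_{j + 1}" for j in range(n_genomes)],
    )
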