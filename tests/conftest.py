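import numpy as np
import pytest

from panpav.synthpop import SimulationConfig, simulate_ancestral_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """One small chromosome; enough features to exercise every track."""
    return SimulationConfig(
        seed=11, n_chromosomes=1, chromosome_length=300_000,
        n_genes=20, n_te=40,
        sv_counts={"DEL": 6, "INS": 6, "INV": 1, "TDUP": 2, "CPX": 1},
        inv_size_range=(20_000, 30_000),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    genome, te_library = simulate_ancestral_genome(small_config)
    return genome, te_library


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
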