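import numpy as np
import pytest

from haplosel.config import GroundTruth, SimulationConfig
from haplosel import simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=12, gene_length=300, flank_length=30, seed=11,
        paralog_fraction=0.25, missing_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    truth = simulate.default_truth(small_config)
    ref = simulate.make_reference(small_config)
    hap, dip = simulate.simulate_cohort(ref, small_config, truth)
    return ref, truth, hap, dip


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230811)
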