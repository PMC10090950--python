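import numpy as np
import pytest

from trail.synthetic_data import DnaSimConfig, SimConfig, simulate_dna_labeling, simulate_proteome_timecourse

TIMEPOINTS = np.array([0.0, 2.0, 4.0, 8.0, 16.0, 32.0])


@pytest.fixture(scope="session")
def noiseless_proteome():
    cfg = SimConfig(n_proteins=40, noise_sigma=0.0, seed=101)
    table, truth = simulate_proteome_timecourse(cfg)
    return table, truth


@pytest.fixture(scope="session")
def noiseless_dna():
    cfg = DnaSimConfig(k_div=0.231, r=0.3, noise_sigma=0.0, seed=202)
    table, truth = simulate_dna_labeling(cfg)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
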