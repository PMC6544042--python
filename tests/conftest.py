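import numpy as np
import pytest

from efp_loopscape.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One shared 100-genome synthetic dataset (decoys, enzymes, noise)."""
    return simulate_dataset(SimulationConfig(n_tips=100, seed=3))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """60 genomes, no backbone noise and no decoys: exact-recovery regime."""
    return simulate_dataset(
        SimulationConfig(n_tips=60, seed=11, backbone_noise_rate=0.0, decoy_fraction=0.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
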