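import numpy as np
import pytest

from gsamda.gat import GATParams
from gsamda.sae import SAEParams
from gsamda.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Planted 30x12 dataset with side matrices: cheap but structured."""
    ds, truth = generate(SynthConfig(n_r=30, n_m=12, n_d=8, seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The planted benchmark conditions used for end-to-end recovery."""
    ds, truth = generate(SynthConfig(seed=7))  # 120x40, 4 blocks
    return ds, truth


@pytest.fixture
def fast_gat_params():
    return GATParams(embed_dim=16, epochs=40, seed=5)


@pytest.fixture
def fast_sae_params():
    return SAEParams(hidden_dim=8, epochs=40, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
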