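import numpy as np
import pytest

from scattn.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def easy_dataset():
    """A small, well-separated 4-class dataset at medium sparsity."""
    cfg = SimConfig(
        n_cells=200, n_genes=120, target_sparsity=0.8, de_prob=0.5, seed=11
    )
    return simulate_counts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
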