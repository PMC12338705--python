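import numpy as np
import pytest

from gxepred.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 lines x 800 variants x 6 environments, default variance targets."""
    cfg = SimulationConfig(n_lines=60, n_variants=800, seed=101)
    geno, pheno, truth = simulate_dataset(cfg)
    return geno, pheno, truth


@pytest.fixture(scope="session")
def tiny_grm():
    """A small dense PSD genomic relationship matrix (20 lines)."""
    rng = np.random.default_rng(7)
    W = rng.choice([0.0, 2.0], size=(20, 400), p=[0.6, 0.4])
    W = W - W.mean(axis=0)
    G = W @ W.T / 200.0
    return G / np.mean(np.diag(G))
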