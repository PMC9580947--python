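import numpy as np
import pytest

from rvmgs import KernelSpec, SimConfig, simulate_genotypes, simulate_phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_binary_X(rng):
    """60 x 12 binary genotype matrix."""
    return rng.integers(0, 2, (60, 12)).astype(float)


@pytest.fixture
def sparse_problem():
    """Small sparse-signal regression problem with known support."""
    rng = np.random.default_rng(99)
    X = rng.integers(0, 2, (120, 40)).astype(float)
    beta = np.zeros(40)
    causal = np.array([5, 17, 31])
    beta[causal] = [2.0, -1.5, 1.0]
    t = X @ beta + rng.normal(0, 0.3, 120)
    return X, t, causal, beta


@pytest.fixture
def sim_pair():
    """Standard synthetic genotype/phenotype pair with truth."""
    cfg = SimConfig(n_individuals=150, n_markers=120, k_causal=6, h2=0.8, seed=5)
    X = simulate_genotypes(cfg)
    t, truth = simulate_phenotype(X, cfg)
    return X, t, truth, cfg


@pytest.fixture
def basis_spec():
    return KernelSpec.linear_basis()
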