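import numpy as np
import pytest

from pcnonp.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_genotypes(rng):
    """Polymorphic random genotype matrix, 12 samples x 30 variants."""
    vals = rng.binomial(2, 0.3, size=(12, 30))
    vals[0, vals.std(axis=0) == 0] = 1  # guarantee polymorphism
    return GenotypeMatrix(vals)


@pytest.fixture
def two_pop_cohort(rng):
    """Two Balding-Nichols subpopulations with clear PC separation."""
    from pcnonp.sim_subpop import SubpopConfig, _freq_matrix, genotype_matrix

    cfg = SubpopConfig(k0=2, n_per_subpop=100, L=1500)
    labels = np.repeat(np.arange(2), cfg.n_per_subpop)
    freqs = _freq_matrix(cfg.L, cfg, rng)
    return GenotypeMatrix(genotype_matrix(freqs, labels, rng)), labels, cfg
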