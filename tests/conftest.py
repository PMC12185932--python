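import numpy as np
import pytest

from owl_divergence import (
    AnalysisConfig,
    GenoSimConfig,
    TraitSimConfig,
    simulate_climate_table,
    simulate_genotypes,
    simulate_trait_table,
)


@pytest.fixture(scope="session")
def small_trait_bundle():
    """Small study-shaped trait table plus its ground truth."""
    cfg = TraitSimConfig(seed=11, n_individuals_per_pop=8)
    table, truth = simulate_trait_table(cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_genotypes():
    cfg = GenoSimConfig(seed=13, n_per_pop=12, theta=0.05, missing_rate=0.05)
    g, freqs = simulate_genotypes(cfg)
    return g, freqs


@pytest.fixture(scope="session")
def small_climate(small_trait_bundle):
    table, _ = small_trait_bundle
    return simulate_climate_table(table.populations, seed=17)


@pytest.fixture
def fast_config():
    return AnalysisConfig(n_permutations=99, seed=23)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(101)
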