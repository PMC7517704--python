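import numpy as np
import pytest

from troutsim import (
    ScenarioConfig,
    assign_trait_architecture,
    build_genetic_map,
    generate_founder_population,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_map():
    return build_genetic_map(n_chromosomes=3, total_length_cM=300.0, n_loci=120, seed=7)


@pytest.fixture(scope="session")
def small_founders(small_map):
    return generate_founder_population(
        80, small_map, maf_low=0.1, maf_high=0.5, n_mixing_generations=5, seed=11
    )


@pytest.fixture(scope="session")
def small_arch(small_map, small_founders):
    return assign_trait_architecture(
        small_map, small_founders, n_qtl=30, r_g=0.8, h2=0.3, seed=13
    )


@pytest.fixture(scope="session")
def micro_config():
    cfg = ScenarioConfig.micro()
    cfg.validate()
    return cfg
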