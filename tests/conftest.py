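import numpy as np
import pytest
from hypothesis import settings

from beanqtl.simulate import PlantedQTL, SimConfig, simulate_population

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_pop():
    """A small population with an observed SNP layer for binmap/pipeline tests:
    40 lines, two 10 Mb chromosomes, ~30 SNPs per 100 Kb window, 1% genotyping
    error, 5% missingness, one planted QTL."""
    cfg = SimConfig(
        n_lines=40,
        chrom_lengths_bp=(10_000_000, 10_000_000),
        snp_density=300.0,
        selfing_generations=6,
        crossover_rate=1.0,
        genotyping_error_rate=0.01,
        missing_rate=0.05,
        qtl_model=(PlantedQTL(chrom=1, position_bp=4_000_000, additive_effect=1.0, target_pve=0.4, trait="ANT"),),
        seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
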