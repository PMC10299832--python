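import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from linkedsel import (
    FitConfig,
    GeneticMap,
    simulate_polymorphism,
)
from linkedsel.synthetic import make_truth_bundle, recovery_config, simulate_genome


@pytest.fixture
def toy_map():
    """Three-point map: pos 0, 1e6, 2e6 at cm 0, 1, 3."""
    return GeneticMap(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [0, 1_000_000, 2_000_000],
                "rate": [1.0, 2.0, 2.0],
                "cm": [0.0, 1.0, 3.0],
            }
        )
    )


@pytest.fixture(scope="session")
def small_genome():
    """2 Mb single-class genome with truth surfaces and kernels (shared)."""
    cfg = recovery_config(seed=11, L=2_000_000, neutral_site_spacing=400)
    genome = simulate_genome(cfg)
    bundle, bk, sk = make_truth_bundle(genome, n_check=60, return_kernels=True)
    return genome, bundle, bk


@pytest.fixture(scope="session")
def small_data(small_genome):
    genome, bundle, _ = small_genome
    return simulate_polymorphism(
        genome.neutral_chrom,
        genome.neutral_pos,
        bundle.pi,
        genome.config.n_chrom_samples,
        seed=1101,
    )


@pytest.fixture(scope="session")
def quick_fit_config():
    return FitConfig(n_starts=3, seed=0)
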