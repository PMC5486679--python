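import numpy as np
import pandas as pd
import pytest

from ldne.genotype_io import GenotypeMatrix, default_samples
from ldne.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small coalescent panel shared by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=40,
        n_chromosomes=2,
        chrom_length_bp=2_000_000,
        target_n_snps=60,
        ne_true=150,
        maf_floor=0.05,
        seed=3,
    )
    return simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_panel(rng, n=20, m=50, missing_rate=0.1):
    """Random (not population-genetic) panel for I/O and counting tests."""
    codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    codes[rng.random((n, m)) < missing_rate] = -1
    chroms = np.repeat(["1", "2"], [m - m // 2, m // 2])
    pos = np.concatenate(
        [
            np.sort(rng.choice(10_000_000, m - m // 2, replace=False)) + 1,
            np.sort(rng.choice(10_000_000, m // 2, replace=False)) + 1,
        ]
    )
    snp_map = pd.DataFrame(
        {
            "chrom": chroms,
            "snp_id": [f"rs{i}" for i in range(m)],
            "genetic_pos": 0.0,
            "physical_pos": pos,
            "allele_a": "A",
            "allele_b": "C",
        }
    )
    return GenotypeMatrix(codes, default_samples(n)), snp_map
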