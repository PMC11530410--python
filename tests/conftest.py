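import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from loadscape.genotypes import GenotypeMatrix
from loadscape.simulate import SimulationConfig, simulate_cohort


def make_matrix(genotypes, chrom="chr1", start_pos=100, spacing=1000) -> GenotypeMatrix:
    """Small GenotypeMatrix from a raw dosage array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(n_sites),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)], sites=sites, genotypes=g
    )


def random_matrix(rng, n_samples=10, n_sites=50, missing_rate=0.1) -> GenotypeMatrix:
    p = rng.uniform(0.05, 0.95, n_sites)
    g = rng.binomial(2, p, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = -1
    return make_matrix(g)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_sites=4000,
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        grid_cell_deg=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)
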