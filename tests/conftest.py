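import numpy as np
import pandas as pd
import pytest

from recmap.genotypes import GenotypeMatrix
from recmap.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_samples=300,
        n_markers_per_chrom=2000,
        n_chroms=1,
        haplotype_freq=0.15,
        mutation_on_haplotype=0.5,
        n_cases=8,
        array_missing_rate=0.002,
        seq_region_n_snps=150,
        seq_region_n_indels=20,
        seq_region_n_outside=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_gm(geno, chroms=None, positions=None, ids=None):
    """Build a GenotypeMatrix from a plain list/array of calls."""
    geno = np.asarray(geno, dtype=np.int8)
    m = geno.shape[1]
    markers = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"m{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
        }
    )
    return GenotypeMatrix(geno=geno, markers=markers)
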