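import numpy as np
import pandas as pd
import pytest

from trionurture.synthetic import SimulationConfig, simulate_cohort
from trionurture.types import GenotypeSet


@pytest.fixture(scope="session")
def small_cohort():
    """A modest trio cohort shared by read-only tests."""
    cfg = SimulationConfig(n_families=200, n_snps=150, seed=2024)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_families=200, n_snps=150, seed=2024)


def make_genotypes(dosages, snp_meta=None, sample_ids=None) -> GenotypeSet:
    """Tiny GenotypeSet builder for hand-written dosage matrices."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if snp_meta is None:
        snp_meta = pd.DataFrame({
            "snp_id": [f"snp{j}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": [1000 * (j + 1) for j in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
        })
    return GenotypeSet(dosages, sample_ids, snp_meta)
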