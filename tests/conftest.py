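import numpy as np
import pandas as pd
import pytest

from cpeparch import SyntheticConfig, simulate_study
from cpeparch.simulate import make_snp_map


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, n_ref=300, n_gwas=4000, n_cohort=600,
                           n_loci=6, n_snps_per_locus=6, n_null_snps=30)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def snp_map(small_config):
    return make_snp_map(small_config)


def random_sumstats(rng, n, chroms=("1", "2"), pos_scale=5_000_000):
    """Random summary-stat records for clustering property tests."""
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "chrom": rng.choice(chroms, size=n),
        "pos": rng.integers(1, pos_scale, size=n),
        "effect_allele": "A",
        "other_allele": "G",
        "beta": rng.normal(size=n),
        "se": np.full(n, 0.1),
        "pvalue": 10.0 ** rng.uniform(-9, -5, size=n),
    })
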