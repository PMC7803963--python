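import numpy as np
import pandas as pd
import pytest

from mwas.simulate import SimConfig, simulate_study
from mwas.types import GenotypeMatrix


@pytest.fixture(scope="session")
def small_study():
    """A small two-cohort study with one planted mQTL metabolite."""
    cfg = SimConfig(n_samples_per_cohort=150, n_snps=100, n_metabolites=6,
                    ld_rho=0.8, h2_per_metabolite=0.3, seed=11,
                    phenotype_gwas_n=5000)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_genotypes(dosages: np.ndarray, chrom=1, bp_step=1000,
                   effect_allele="A", other_allele="G") -> GenotypeMatrix:
    """Wrap a raw dosage array in a GenotypeMatrix with simple metadata."""
    n, m = dosages.shape
    f = dosages.mean(axis=0) / 2.0
    meta = pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)],
        "chr": chrom, "bp": np.arange(m) * bp_step + 1,
        "effect_allele": effect_allele, "other_allele": other_allele,
        "maf": np.minimum(f, 1 - f),
    })
    return GenotypeMatrix(dosages.astype(float), meta,
                          pd.Index([f"i{k}" for k in range(n)]))
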