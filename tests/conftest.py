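import numpy as np
import pandas as pd
import pytest

from mireqtl import ExpressionMatrix, GenotypeMatrix, SimulationConfig, compute_maf
from mireqtl.core import SNP_COLUMNS
from mireqtl.simulate import simulate_cohort


def make_genotypes(dosage: np.ndarray, mafs=None, alleles=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw sample x SNP dosage array."""
    n, p = dosage.shape
    snp_ids = [f"rs{j + 1}" for j in range(p)]
    alleles = alleles or [("A", "G")] * p
    snps = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": "1",
        "pos": np.arange(1, p + 1),
        "ref_allele": [a[0] for a in alleles],
        "alt_allele": [a[1] for a in alleles],
        "maf": np.nan,
        "hwe_p": np.nan,
    })[SNP_COLUMNS]
    g = GenotypeMatrix(
        pd.DataFrame(dosage.astype(float),
                     index=[f"S{i + 1}" for i in range(n)], columns=snp_ids),
        snps,
    )
    return compute_maf(g)


def make_expression(values: np.ndarray, kind: str = "miRNA",
                    prefix: str = "f") -> ExpressionMatrix:
    m, n = values.shape
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"{prefix}{i + 1}" for i in range(m)],
                     columns=[f"S{j + 1}" for j in range(n)]),
        kind,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort with planted eQTLs, regulations and catalog."""
    cfg = SimulationConfig(
        n_samples=79, n_snps=400, n_mirnas=40, n_low_quality_mirnas=10,
        n_mrnas=120, n_planted_eqtls=6, n_planted_regulations=15,
        n_hidden_factors=4, catalog_size=30, catalog_fraction_overlapping=0.2,
        missingness_rate=0.05, seed=11,
    )
    return simulate_cohort(cfg)
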