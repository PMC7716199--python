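import numpy as np
import pandas as pd
import pytest

from admixscan import (GenotypeMatrix, PhenotypeTable, RunConfig, SNPInfo,
                       SimulationConfig, simulate_dataset)


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale simulated cohort (176 cases / 183 controls, 141 SNPs)
    with the default planted effects and confounding."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_null_dataset():
    """A small cohort with no genetic effects and no confounder bias."""
    from admixscan import null_config
    cfg = null_config(n_cases=120, n_controls=130, n_snps=30,
                      confounded=False, seed=5)
    return simulate_dataset(cfg)


def make_matrix(dosages, sample_prefix="S", snp_prefix="snp"):
    """Build a GenotypeMatrix around a raw dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    snps = [SNPInfo(f"{snp_prefix}{j}", "1", 1000 + j, "A", "G")
            for j in range(m)]
    return GenotypeMatrix(samples, snps, dosages)


def make_pheno(n, n_cases=None, rng=None, sample_prefix="S"):
    """A benign phenotype table: balanced covariates, Dirichlet ancestry."""
    rng = rng or np.random.default_rng(0)
    if n_cases is None:
        n_cases = n // 2
    anc = rng.dirichlet((8.0, 1.0, 1.0), size=n)
    df = pd.DataFrame({
        "status": ["case"] * n_cases + ["control"] * (n - n_cases),
        "age": rng.normal(60, 8, n).clip(45, None),
        "bmi": rng.normal(26, 4, n),
        "anc_eur": anc[:, 0], "anc_afr": anc[:, 1], "anc_nat": anc[:, 2],
        "ses": rng.integers(1, 4, n),
        "education": rng.integers(1, 4, n),
    }, index=pd.Index([f"{sample_prefix}{i}" for i in range(n)],
                      name="sample_id"))
    return PhenotypeTable(df)
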