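import numpy as np
import pandas as pd
import pytest

from bivargwas.data import StudyDataset


def make_pheno(n, rng, m_pre=5.3, m_post=5.0, scale=0.15):
    """Small phenotype/covariate table with log-normal raw lipids."""
    lat_x = rng.normal(size=n)
    lat_y = 0.6 * lat_x + 0.8 * rng.normal(size=n)
    return pd.DataFrame(
        {
            "pre": np.exp(m_pre + scale * lat_x),
            "post": np.exp(m_post + scale * lat_y),
            "bmi": np.exp(rng.normal(np.log(28), 0.15, n)),
            "age": rng.normal(60, 10, n),
            "sex": rng.binomial(1, 0.6, n).astype(float),
            "smoking": rng.binomial(1, 0.2, n).astype(float),
        },
        index=pd.Index([f"id{i:04d}" for i in range(n)], name="id"),
    )


def make_study(n=120, m=5, maf=0.3, seed=0, study_id="toy"):
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, maf, size=(n, m)).astype(float)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{j}" for j in range(m)],
            "chrom": 1,
            "pos": (np.arange(m) + 1) * 50_000,
            "allele1": "A",
            "allele0": "G",
        }
    )
    return StudyDataset(
        study_id=study_id,
        dosages=geno,
        pheno=make_pheno(n, rng),
        snps=snps,
        het_probs=(geno == 1).astype(float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_study():
    return make_study()
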