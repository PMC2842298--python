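"""Multi-study synthetic genotype/phenotype generator.

Emulates the statistical structure of a multi-trial statin pharmacogenomic
dataset: several studies of different sizes with study-specific raw-scale
locations and scales, Hardy-Weinberg genotypes at per-study allele
frequencies, log-normal raw lipid measurements built from latent sum (S*)
and difference (D*) traits, covariate effects, imputation-style dosage
noise, and planted SNP effects of three classes:

* ``null`` — no effect on either trait;
* ``statin_independent`` — affects the sum trait only (same effect on pre-
  and post-treatment levels);
* ``statin_response`` — affects the difference trait (and possibly the sum).

Effect sizes are specified as the fraction of latent-trait variance the SNP
explains, the only effect-size currency the analysis itself reports.
Latent traits are mapped to raw scales via ``X_raw = exp(m_pre + s (S* -
D*)/2)`` and ``Y_raw = exp(m_post + s (S* + D*)/2)``, so the raw values are
log-normal and strictly monotone in the latent values — the downstream
rank-based normalization is invariant to the per-study affine parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import StudyDataset

__all__ = [
    "SimConfig",
    "default_config",
    "simulate_genotypes",
    "simulate_study",
    "simulate_multistudy",
]

EFFECT_CLASSES = ("null", "statin_independent", "statin_response")

#: Per-study (m_pre, m_post, s) for the raw log scale, loosely matched to
#: the total-cholesterol rows of the three trials' population tables
#: (means ~212/153, 215/174, 245/174 mg/dL; log-scale sd ~ 0.16).
DEFAULT_STUDY_AFFINE = (
    (5.357, 5.033, 0.16),
    (5.372, 5.156, 0.17),
    (5.502, 5.160, 0.12),
)

#: Study sizes matching the combined trial sample of 3,932 Caucasian
#: participants split across the three trials.
DEFAULT_N_PER_STUDY = (592, 1364, 1976)


@dataclass
class SimConfig:
    """Configuration of one multi-study simulation.

    ``var_explained_s`` / ``var_explained_d`` give each SNP's target share
    of latent S* / D* variance; the generator converts them to regression
    coefficients using the per-study dosage variance.  ``effect_classes``
    constrains them: ``null`` forces both to zero and
    ``statin_independent`` forces the D share to zero.
    """

    n_snps: int = 10
    n_per_study: tuple = DEFAULT_N_PER_STUDY
    maf: np.ndarray | float = 0.24
    maf_jitter_sd: float = 0.01
    effect_classes: tuple | None = None
    var_explained_s: np.ndarray | float = 0.0
    var_explained_d: np.ndarray | float = 0.0
    covariate_effects_s: dict = field(
        default_factory=lambda: {"log_bmi": 0.5, "age": 0.01, "sex": -0.2, "smoking": 0.1}
    )
    covariate_effects_d: dict = field(
        default_factory=lambda: {"log_bmi": 0.2, "age": 0.005, "sex": -0.1, "smoking": 0.05}
    )
    study_affine: tuple = DEFAULT_STUDY_AFFINE
    imputation_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.maf = np.broadcast_to(
            np.asarray(self.maf, dtype=float), (self.n_snps,)
        ).copy()
        if (self.maf <= 0).any() or (self.maf > 0.5).any():
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        if not 0.0 <= self.imputation_noise <= 1.0:
            raise ValueError("imputation_noise must lie in [0, 1]")
        if self.effect_classes is None:
            self.effect_classes = tuple(["null"] * self.n_snps)
        if len(self.effect_classes) != self.n_snps:
            raise ValueError("one effect class per SNP required")
        bad = set(self.effect_classes) - set(EFFECT_CLASSES)
        if bad:
            raise ValueError(f"unknown effect classes: {sorted(bad)}")
        self.var_explained_s = np.broadcast_to(
            np.asarray(self.var_explained_s, dtype=float), (self.n_snps,)
        ).copy()
        self.var_explained_d = np.broadcast_to(
            np.asarray(self.var_explained_d, dtype=float), (self.n_snps,)
        ).copy()
        cls = np.asarray(self.effect_classes)
        self.var_explained_s[cls == "null"] = 0.0
        self.var_explained_d[cls == "null"] = 0.0
        self.var_explained_d[cls == "statin_independent"] = 0.0
        for name, ve in (("S", self.var_explained_s), ("D", self.var_explained_d)):
            if (ve < 0).any():
                raise ValueError("variance-explained targets must be >= 0")
            if ve.sum() >= 1.0:
                raise ValueError(
                    f"variance-explained targets for {name} sum to >= 1"
                )
        if len(self.study_affine) != self.n_studies:
            raise ValueError("need one (m_pre, m_post, s) triple per study")

    @property
    def n_studies(self) -> int:
        return len(self.n_per_study)


def default_config(**overrides) -> SimConfig:
    """Three-study configuration mirroring the combined-trial conditions."""
    return SimConfig(**overrides)


def simulate_genotypes(maf: float, n: int, noise: float = 0.0, rng=None):
    """HWE genotypes with imputation-style shrinkage toward 2*MAF.

    Hard genotypes are Binomial(2, maf); the returned dosage is the blend
    ``(1 - r) * genotype + r * 2 * maf`` with ``r = noise``, which preserves
    the mean while attenuating information (``r = 1`` is fully
    uninformative).  Heterozygote probabilities are blended the same way
    (exactly 1 for heterozygotes when r = 0).
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise weight must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    geno = rng.binomial(2, maf, size=n).astype(float)
    dosage = (1.0 - noise) * geno + noise * 2.0 * maf
    het = (1.0 - noise) * (geno == 1.0) + noise * 2.0 * maf * (1.0 - maf)
    return dosage, het


def _study_mafs(config: SimConfig, study_index: int) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7919, study_index])
    )
    jitter = rng.normal(0.0, config.maf_jitter_sd, size=config.n_snps)
    return np.clip(config.maf + jitter, 0.01, 0.5)


def simulate_study(config: SimConfig, study_index: int) -> StudyDataset:
    """Generate one study's dataset; deterministic given (seed, index)."""
    if not 0 <= study_index < config.n_studies:
        raise ValueError("study_index out of range")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, study_index])
    )
    n = int(config.n_per_study[study_index])
    m = config.n_snps
    r = config.imputation_noise
    mafs = _study_mafs(config, study_index)

    geno = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    dosages = (1.0 - r) * geno + r * 2.0 * mafs[None, :]
    het = (1.0 - r) * (geno == 1.0) + r * 2.0 * mafs[None, :] * (
        1.0 - mafs[None, :]
    )

    # covariates: distributions loosely matched to the trials' population
    # tables; exact values are immaterial because normalization removes them
    age = rng.normal(60.0, 10.0, size=n)
    bmi = np.exp(rng.normal(np.log(28.0), 0.17, size=n))
    sex = rng.binomial(1, 0.7, size=n).astype(float)
    smoking = rng.binomial(1, 0.15, size=n).astype(float)
    cov = {"log_bmi": np.log(bmi), "age": age, "sex": sex, "smoking": smoking}

    def latent(ve, coeffs, noise_vec):
        cov_term = sum(c * cov[k] for k, c in coeffs.items())
        var_cov = float(np.var(sum(c * cov[k] for k, c in coeffs.items())))
        var_total = (1.0 + var_cov) / (1.0 - ve.sum())
        var_g = (1.0 - r) ** 2 * 2.0 * mafs * (1.0 - mafs)
        beta = np.sqrt(np.divide(
            ve * var_total, var_g, out=np.zeros(m), where=var_g > 0
        ))
        raw = dosages @ beta + cov_term + noise_vec
        return raw / np.sqrt(var_total), beta

    eps_s = rng.normal(0.0, 1.0, size=n)
    eps_d = rng.normal(0.0, 1.0, size=n)
    s_lat, _ = latent(config.var_explained_s, config.covariate_effects_s, eps_s)
    d_lat, _ = latent(config.var_explained_d, config.covariate_effects_d, eps_d)

    m_pre, m_post, s_scale = config.study_affine[study_index]
    x_raw = np.exp(m_pre + s_scale * (s_lat - d_lat) / 2.0)
    y_raw = np.exp(m_post + s_scale * (s_lat + d_lat) / 2.0)

    ids = [f"S{study_index}_{i:05d}" for i in range(n)]
    pheno = pd.DataFrame(
        {
            "pre": x_raw,
            "post": y_raw,
            "bmi": bmi,
            "age": age,
            "sex": sex,
            "smoking": smoking,
        },
        index=pd.Index(ids, name="id"),
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:06d}" for j in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": (np.arange(m) + 1) * 100_000,
            "allele1": "A",
            "allele0": "G",
            "maf": mafs,
        }
    )
    return StudyDataset(
        study_id=f"study{study_index}",
        dosages=dosages,
        pheno=pheno,
        snps=snps,
        het_probs=het,
    )


def simulate_multistudy(config: SimConfig) -> list[StudyDataset]:
    """All studies of the configuration, each deterministic given the seed."""
    return [simulate_study(config, k) for k in range(config.n_studies)]
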