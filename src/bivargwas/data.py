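"""Core data containers shared across the pipeline.

A :class:`StudyDataset` holds one study's genotype dosages, raw pre/post
phenotype measurements and covariates; it is the unit on which phenotype
normalization operates.  :class:`NormalizedTraits` holds the final
per-individual sum (S) and difference (D) scores produced by the four-step
normalization pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["pre", "post", "bmi", "age", "sex", "smoking"]
SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele0"]


@dataclass
class StudyDataset:
    """One study's genotypes, raw phenotypes and covariates.

    Parameters
    ----------
    study_id : str
        Label for the study (normalization unit).
    dosages : ndarray, shape (n_individuals, n_snps)
        Posterior mean genotypes (expected minor-allele counts) in [0, 2].
    pheno : DataFrame
        One row per individual, indexed by individual id, with columns
        ``pre``, ``post`` (raw-scale, strictly positive phenotype values),
        ``bmi`` (kg/m^2, > 0), ``age`` (years), ``sex`` (0/1) and
        ``smoking`` (0/1).
    snps : DataFrame
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos``,
        ``allele1`` (minor), ``allele0`` (major) and optionally ``maf``.
    het_probs : ndarray or None, shape (n_individuals, n_snps)
        Per-individual heterozygote probabilities in [0, 1].  ``None`` when
        the genotype source provides dosages only; the dominance column of
        the Bayesian model is then unavailable.
    """

    study_id: str
    dosages: np.ndarray
    pheno: pd.DataFrame
    snps: pd.DataFrame
    het_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x SNPs) array")
        n, m = self.dosages.shape
        if len(self.pheno) != n:
            raise ValueError(
                f"phenotype table has {len(self.pheno)} rows but dosage "
                f"matrix has {n} individuals"
            )
        if len(self.snps) != m:
            raise ValueError(
                f"SNP table has {len(self.snps)} rows but dosage matrix has "
                f"{m} SNPs"
            )
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")
        if self.het_probs is not None:
            self.het_probs = np.asarray(self.het_probs, dtype=float)
            if self.het_probs.shape != self.dosages.shape:
                raise ValueError("het_probs shape must match dosages")
            if self.het_probs.size and (
                self.het_probs.min() < -1e-9 or self.het_probs.max() > 1 + 1e-9
            ):
                raise ValueError("het_probs must lie in [0, 1]")
        for col in ("pre", "post"):
            vals = self.pheno[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | (vals > 0)
            if not ok.all():
                raise ValueError(f"raw phenotype column {col!r} must be > 0")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class NormalizedTraits:
    """Final per-individual S and D scores for one dataset.

    Both vectors are rank-inverse-normal scores: within the dataset each has
    empirical mean ~0 and marginal quantiles matching the standard normal.
    ``corr_sd`` records the (not enforced) residual correlation between S
    and D after the pipeline; the method assumes it is negligible.
    """

    dataset_id: str
    S: np.ndarray
    D: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    corr_sd: float = float("nan")

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.S.shape != self.D.shape:
            raise ValueError("S and D must have the same length")
        if self.ids is None:
            self.ids = np.arange(len(self.S))
        self.ids = np.asarray(self.ids)

    def __len__(self) -> int:
        return len(self.S)
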