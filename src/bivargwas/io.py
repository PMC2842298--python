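"""Readers and writers for the scan's text formats.

Genotypes travel as BIMBAM mean-genotype text (one row per SNP: id, minor
allele, major allele, then one dosage in [0, 2] per individual) or as VCF
with a per-genotype dosage (DS) field.  Phenotypes/covariates and SNP
metadata are TSV with headers; run configuration is YAML.

Alleles are recorded as (minor, major) with dosage counting the minor
allele; a file whose dosage frequency exceeds 0.5 is flipped on read
(g -> 2 - g, alleles swapped) and the flip is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import PHENO_COLUMNS, StudyDataset

__all__ = [
    "read_bimbam",
    "write_bimbam",
    "read_genotypes",
    "read_pheno",
    "write_pheno",
    "read_snp_table",
    "write_snp_table",
    "write_scan",
    "load_study",
    "save_study",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger("bivargwas")

SCAN_FLOAT_FORMAT = "%.6g"


def read_bimbam(path):
    """Parse a BIMBAM mean-genotype file.

    Returns ``(dosages, snps)`` with dosages shaped (individuals x SNPs)
    and ``snps`` a DataFrame with snp_id/allele1/allele0.  Errors carry the
    offending line number.
    """
    ids, a1s, a0s, rows = [], [], [], []
    n_ind = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected id, 2 alleles and >= 1 dosage"
                )
            snp_id, a1, a0 = parts[0], parts[1], parts[2]
            try:
                dos = np.array(parts[3:], dtype=float)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric dosage field ({exc})"
                ) from None
            if n_ind is None:
                n_ind = len(dos)
            elif len(dos) != n_ind:
                raise ValueError(
                    f"{path}:{lineno}: {len(dos)} dosages, expected {n_ind}"
                )
            if dos.min() < 0 or dos.max() > 2:
                raise ValueError(
                    f"{path}:{lineno}: dosage outside [0, 2]"
                )
            ids.append(snp_id)
            a1s.append(a1)
            a0s.append(a0)
            rows.append(dos)
    if not rows:
        raise ValueError(f"{path}: empty genotype file")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:10]
        raise ValueError(f"{path}: duplicate SNP ids {dupes}")
    dosages = np.array(rows).T
    snps = pd.DataFrame({"snp_id": ids, "allele1": a1s, "allele0": a0s})
    return _flip_major_coded(dosages, snps)


def _flip_major_coded(dosages, snps):
    """Flip columns counting the major allele so dosage counts the minor."""
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        flipped = snps.loc[flip, "snp_id"].tolist()
        logger.info(
            "flipped %d SNP(s) coded on the major allele: %s%s",
            int(flip.sum()),
            ", ".join(flipped[:5]),
            "..." if len(flipped) > 5 else "",
        )
        dosages = dosages.copy()
        dosages[:, flip] = 2.0 - dosages[:, flip]
        snps = snps.copy()
        a1 = snps.loc[flip, "allele1"].copy()
        snps.loc[flip, "allele1"] = snps.loc[flip, "allele0"].to_numpy()
        snps.loc[flip, "allele0"] = a1.to_numpy()
    return dosages, snps


def write_bimbam(dosages, snps, path) -> None:
    """Write dosages (individuals x SNPs) as BIMBAM mean-genotype text."""
    dosages = np.asarray(dosages, dtype=float)
    with open(path, "w") as fh:
        for j in range(dosages.shape[1]):
            row = snps.iloc[j]
            dos = " ".join(f"{v:.6g}" for v in dosages[:, j])
            fh.write(f"{row['snp_id']} {row['allele1']} {row['allele0']} {dos}\n")


def read_vcf_dosages(path):
    """Dosages + SNP metadata from a VCF carrying a per-genotype DS field."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, chroms, poss, a1s, a0s, rows = [], [], [], [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(
                f"{path}: record {var.ID or var.POS} lacks a DS dosage field"
            )
        dos = np.asarray(ds, dtype=float).ravel()
        if dos.min() < 0 or dos.max() > 2:
            raise ValueError(f"{path}: dosage outside [0, 2] at {var.ID}")
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        a1s.append(var.ALT[0] if var.ALT else ".")
        a0s.append(var.REF)
        rows.append(dos)
    if not rows:
        raise ValueError(f"{path}: no variant records")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate SNP ids")
    dosages = np.array(rows).T
    snps = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "pos": poss,
            "allele1": a1s,
            "allele0": a0s,
        }
    )
    return _flip_major_coded(dosages, snps)


def read_genotypes(path, fmt: str = "bimbam"):
    """Dispatch on format: ``bimbam`` (mean-genotype text) or ``vcf``."""
    if fmt == "bimbam":
        return read_bimbam(path)
    if fmt == "vcf":
        return read_vcf_dosages(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_pheno(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table lacks columns {missing}")
    if "id" in df.columns:
        df = df.set_index("id")
    return df


def write_pheno(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="id")


def read_snp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def write_scan(table: pd.DataFrame, path) -> None:
    """Scan results as TSV with stable column order, 6 significant digits."""
    lead = [
        "snp_id",
        "chrom",
        "pos",
        "maf",
        "post_H0",
        "post_HS",
        "post_HD",
        "post_HSD",
        "response_prob",
        "p_S",
        "p_D",
        "beta_S",
        "se_S",
        "beta_D",
        "se_D",
        "log10_bf_S",
        "log10_bf_D",
    ]
    cols = [c for c in lead if c in table.columns] + sorted(
        c for c in table.columns if c not in lead
    )
    table[cols].to_csv(
        path, sep="\t", index=False, float_format=SCAN_FLOAT_FORMAT
    )


def load_study(
    study_id: str,
    genotypes,
    pheno,
    snps=None,
    fmt: str = "bimbam",
) -> StudyDataset:
    """Assemble a StudyDataset from on-disk files."""
    dosages, snp_alleles = read_genotypes(genotypes, fmt)
    if snps is not None:
        meta = read_snp_table(snps)
        if len(meta) != snp_alleles.shape[0] or (
            meta["snp_id"].to_numpy() != snp_alleles["snp_id"].to_numpy()
        ).any():
            raise ValueError(
                f"SNP metadata in {snps} does not match genotype file order"
            )
        snp_table = meta
    else:
        snp_table = snp_alleles.assign(chrom=np.nan, pos=np.nan)
    return StudyDataset(
        study_id=study_id,
        dosages=dosages,
        pheno=read_pheno(pheno),
        snps=snp_table,
    )


def save_study(study: StudyDataset, outdir) -> dict:
    """Write one study's files; returns a manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = outdir / f"{study.study_id}.bimbam.txt"
    phen = outdir / f"{study.study_id}.pheno.tsv"
    meta = outdir / f"{study.study_id}.snps.tsv"
    write_bimbam(study.dosages, study.snps, geno)
    write_pheno(study.pheno, phen)
    write_snp_table(study.snps, meta)
    return {
        "study_id": study.study_id,
        "genotypes": str(geno),
        "pheno": str(phen),
        "snps": str(meta),
    }


@dataclass
class RunConfig:
    """Whole-run configuration loaded from YAML."""

    datasets: list = field(default_factory=list)
    traits: list = field(default_factory=lambda: ["tc"])
    sigma_grid: list = field(
        default_factory=lambda: [0.05, 0.075, 0.1, 0.125, 0.15, 0.2, 0.4]
    )
    sigma_d_ratio: float = 0.25
    priors: list = field(
        default_factory=lambda: [1.0 - 1e-4, 0.9e-4, 0.01e-4, 0.09e-4]
    )
    region_window_kb: float = 500.0
    h0_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        priors = np.asarray(self.priors, dtype=float)
        if abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        for entry in self.datasets:
            for key in ("genotypes", "pheno"):
                if key in entry and not Path(entry[key]).exists():
                    raise FileNotFoundError(entry[key])


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
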