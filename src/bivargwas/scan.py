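"""Genome-scan orchestration and reporting.

:class:`ResponseScan` is the model object: it is built from a list of
per-study datasets plus a :class:`ScanConfig` and its :meth:`ResponseScan.fit`
runs the full pipeline — per-dataset normalization, per-dataset and
fixed-effects-combined Bayes factors for the sum (S) and difference (D)
traits, four-model posteriors, and the frequentist companion tests — and
returns a :class:`ScanResults` carrying the per-SNP table, genomic-control
diagnostics and reporting helpers (top regions, posterior-expected
association counts, QQ data, summary table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes, freq
from .data import StudyDataset
from .normalize import normalize_dataset

__all__ = [
    "ScanConfig",
    "ResponseScan",
    "ScanResults",
    "run_scan",
    "filter_top",
    "group_regions",
    "expected_association_count",
]


@dataclass
class ScanConfig:
    """Analysis settings for one scan.

    ``region_window_kb`` is the merge window used when collapsing nearby
    SNPs into regions for reporting (the analysis itself is per-SNP).
    """

    sigma_grid: tuple = bayes.DEFAULT_SIGMA_GRID
    sigma_d_ratio: float = bayes.DEFAULT_SIGMA_D_RATIO
    priors: tuple = bayes.DEFAULT_PRIORS
    region_window_kb: float = 500.0
    h0_threshold: float = 0.5

    def __post_init__(self) -> None:
        priors = np.asarray(self.priors, dtype=float)
        if priors.shape != (4,) or abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must be 4 probabilities summing to 1")


def _check_alignment(studies) -> pd.DataFrame:
    ref = studies[0].snps["snp_id"].to_numpy()
    if len(set(ref)) != len(ref):
        raise ValueError("duplicate SNP ids in study panel")
    for st in studies[1:]:
        ids = st.snps["snp_id"].to_numpy()
        if len(ids) != len(ref) or (ids != ref).any():
            offenders = sorted(set(ref).symmetric_difference(ids))[:10]
            raise ValueError(
                f"SNP panels differ between {studies[0].study_id} and "
                f"{st.study_id}; offending ids (first 10): {offenders}"
            )
    return studies[0].snps


def run_scan(
    studies: list[StudyDataset],
    config: ScanConfig | None = None,
    trait: str = "D",
) -> pd.DataFrame:
    """Scan all SNPs; one output row per SNP.

    ``trait`` is ignored for the Bayesian columns (both S and D always
    enter the model space); it is kept for symmetry with the CLI.
    Deterministic given inputs.
    """
    config = config or ScanConfig()
    if not studies:
        raise ValueError("need at least one study")
    snps = _check_alignment(studies)
    m = len(snps)

    stats_s, stats_d = [], []
    per_study_bf = {}
    pooled_s, pooled_d, pooled_g = [], [], []
    mafs, sizes = {}, {}
    for st in studies:
        traits = normalize_dataset(st)
        idx = st.pheno.index.get_indexer(traits.ids)
        if (idx < 0).any():
            bad = np.asarray(traits.ids)[idx < 0][:10]
            raise ValueError(f"individual ids not in phenotype table: {bad}")
        G = st.dosages[idx]
        H = st.het_probs[idx] if st.het_probs is not None else None
        ss = bayes.dataset_sufficient_stats(traits.S, G, H)
        sd = bayes.dataset_sufficient_stats(traits.D, G, H)
        stats_s.append(ss)
        stats_d.append(sd)
        per_study_bf[f"log10_bf_S_{st.study_id}"] = bayes.log10_bf_grid_average(
            ss, config.sigma_grid, config.sigma_d_ratio
        )
        per_study_bf[f"log10_bf_D_{st.study_id}"] = bayes.log10_bf_grid_average(
            sd, config.sigma_grid, config.sigma_d_ratio
        )
        pooled_s.append(traits.S)
        pooled_d.append(traits.D)
        pooled_g.append(G)
        mafs[st.study_id] = G.mean(axis=0) / 2.0
        sizes[st.study_id] = len(traits)

    bf_s = bayes.bf_combined_grid_average(
        stats_s, config.sigma_grid, config.sigma_d_ratio
    )
    bf_d = bayes.bf_combined_grid_average(
        stats_d, config.sigma_grid, config.sigma_d_ratio
    )
    post = bayes.model_posteriors_array(bf_s, bf_d, config.priors)

    t_s = np.concatenate(pooled_s)
    t_d = np.concatenate(pooled_d)
    G_all = np.vstack(pooled_g)
    beta_s, se_s, p_s = freq.lm_pvalues_matrix(t_s, G_all)
    beta_d, se_d, p_d = freq.lm_pvalues_matrix(t_d, G_all)

    gc = G_all - G_all.mean(axis=0)
    mono = np.einsum("ij,ij->j", gc, gc) <= 1e-12
    # monomorphic-in-all-datasets SNPs carry no evidence: BF = 1,
    # posteriors = priors, frequentist result missing
    bf_s = np.where(mono, 0.0, bf_s)
    bf_d = np.where(mono, 0.0, bf_d)
    post[mono] = np.asarray(config.priors, dtype=float)

    total_n = sum(sizes.values())
    maf_overall = sum(sizes[k] * v for k, v in mafs.items()) / total_n

    table = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "maf": maf_overall,
            **{f"maf_{k}": v for k, v in mafs.items()},
            "post_H0": post[:, 0],
            "post_HS": post[:, 1],
            "post_HD": post[:, 2],
            "post_HSD": post[:, 3],
            "response_prob": post[:, 2] + post[:, 3],
            "p_S": p_s,
            "p_D": p_d,
            "beta_S": beta_s,
            "se_S": se_s,
            "beta_D": beta_d,
            "se_D": se_d,
            "log10_bf_S": bf_s,
            "log10_bf_D": bf_d,
            **per_study_bf,
            "monomorphic": mono,
        }
    )
    return table


def filter_top(table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Rows with posterior probability of no association below threshold."""
    return table[table["post_H0"] < threshold].copy()


def group_regions(table: pd.DataFrame, window_kb: float = 500.0) -> pd.DataFrame:
    """One representative SNP per region.

    SNPs on the same chromosome within ``window_kb`` of each other (chained)
    are merged; the representative is the row with the smallest P(H0), ties
    broken by smaller p-value on the relevant trait (p_D when the row's
    evidence favors a response association, p_S otherwise), then by
    position.
    """
    if table.empty:
        return table.copy()
    df = table.copy()
    missing_pos = df["pos"].isna() | df["chrom"].isna()
    if missing_pos.any():
        import warnings

        warnings.warn(
            f"{int(missing_pos.sum())} rows lack positions; "
            "each is treated as its own region",
            stacklevel=2,
        )
    window = window_kb * 1000.0
    reps = []
    placed = df[~missing_pos].sort_values(["chrom", "pos"])
    for _, grp in placed.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        breaks = np.r_[0, np.nonzero(np.diff(pos) > window)[0] + 1, len(pos)]
        for a, b in zip(breaks[:-1], breaks[1:]):
            block = grp.iloc[a:b]
            rel_p = np.where(
                block["response_prob"] >= 0.5, block["p_D"], block["p_S"]
            )
            order = np.lexsort(
                (block["pos"].to_numpy(), rel_p, block["post_H0"].to_numpy())
            )
            reps.append(block.iloc[order[0]])
    for _, row in df[missing_pos].iterrows():
        reps.append(row)
    return pd.DataFrame(reps).reset_index(drop=True)


def expected_association_count(table: pd.DataFrame) -> dict:
    """Posterior-expected numbers of associated SNPs in the table.

    Returns the expected count of response associations (sum of
    ``response_prob``) and of associations of any kind (sum of 1 - P(H0)).
    """
    return {
        "response": float(table["response_prob"].sum()),
        "any": float((1.0 - table["post_H0"]).sum()),
    }


class ResponseScan:
    """Bivariate sum/difference association scan over multiple studies.

    Parameters
    ----------
    studies : list of StudyDataset
        Per-study genotypes + raw phenotypes; each study is normalized
        independently before the fixed-effects combination.
    config : ScanConfig, optional
        Prior grid, model-space priors and reporting thresholds.
    """

    def __init__(self, studies, config: ScanConfig | None = None):
        self.studies = list(studies)
        self.config = config or ScanConfig()

    @classmethod
    def from_files(cls, manifest, config: ScanConfig | None = None):
        """Build from a dataset manifest (see :func:`bivargwas.io.load_study`)."""
        from . import io

        studies = [io.load_study(**entry) for entry in manifest]
        return cls(studies, config)

    def fit(self) -> "ScanResults":
        table = run_scan(self.studies, self.config)
        return ScanResults(table=table, config=self.config, model=self)


@dataclass
class ScanResults:
    """Fitted scan: per-SNP table plus diagnostics and reporting."""

    table: pd.DataFrame
    config: ScanConfig
    model: ResponseScan | None = field(default=None, repr=False)

    @property
    def lambda_gc(self) -> dict:
        """Genomic-control inflation factors for the S and D tests."""
        return {
            "S": freq.genomic_control_lambda(self.table["p_S"].dropna()),
            "D": freq.genomic_control_lambda(self.table["p_D"].dropna()),
        }

    def qq_points(self, trait: str = "D"):
        return freq.qq_points(self.table[f"p_{trait}"].dropna())

    def top_regions(
        self, threshold: float | None = None, window_kb: float | None = None
    ) -> pd.DataFrame:
        """Regions with posterior probability of no association < threshold,
        one representative SNP each."""
        threshold = self.config.h0_threshold if threshold is None else threshold
        window_kb = (
            self.config.region_window_kb if window_kb is None else window_kb
        )
        return group_regions(filter_top(self.table, threshold), window_kb)

    def expected_association_counts(self) -> dict:
        return expected_association_count(self.table)

    def plot_qq(self, path=None, trait: str = "D"):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        exp, obs = self.qq_points(trait)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(exp, obs, ".", ms=2)
        lim = max(exp.max(), obs.max())
        ax.plot([0, lim], [0, lim], "k-", lw=0.8)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"{trait} trait (lambda = {self.lambda_gc[trait]:.3f})")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def to_tsv(self, path) -> None:
        from . import io

        io.write_scan(self.table, path)

    def summary(self, threshold: float | None = None) -> str:
        """Plain-text report of the strongest regions and expected counts."""
        top = self.top_regions(threshold)
        counts = self.expected_association_counts()
        lam = self.lambda_gc
        lines = [
            "Bivariate sum/difference association scan",
            f"  SNPs scanned: {len(self.table)}"
            f"  (monomorphic: {int(self.table['monomorphic'].sum())})",
            f"  genomic control lambda: S {lam['S']:.3f}, D {lam['D']:.3f}",
            f"  posterior-expected associations: "
            f"any {counts['any']:.2f}, response {counts['response']:.2f}",
            f"  regions with P(H0) < "
            f"{self.config.h0_threshold if threshold is None else threshold}: "
            f"{len(top)}",
        ]
        if len(top):
            cols = [
                "snp_id",
                "chrom",
                "pos",
                "post_H0",
                "post_HS",
                "post_HD",
                "post_HSD",
                "p_S",
                "p_D",
                "maf",
            ]
            lines.append(top[cols].to_string(index=False))
        return "\n".join(lines)
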