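"""Four-step per-dataset phenotype normalization producing S and D traits.

Within each dataset (one study x genotyping-stage block):

1. rank-inverse-normal transform the raw pre- and post-treatment values;
2. form the sum S = post + pre and difference D = post - pre;
3. residualize S and D on the covariates (log(BMI), age, sex, smoking) by
   ordinary least squares;
4. rank-inverse-normal transform each residual vector again.

Because only ranks enter, any strictly increasing transform of the raw
values leaves the output unchanged, and datasets of equal size share an
identical multiset of scores — allele-frequency differences between studies
therefore cannot create spurious associations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data import NormalizedTraits, StudyDataset

__all__ = [
    "average_repeats",
    "rank_inverse_normal",
    "sum_diff",
    "adjust_covariates",
    "normalize_dataset",
]

COVARIATE_COLUMNS = ("log_bmi", "age", "sex", "smoking")


def average_repeats(measurements) -> float:
    """Mean of the non-missing per-visit values for one individual.

    Returns NaN (individual flagged missing) when every visit is missing.
    """
    vals = np.asarray(measurements, dtype=float)
    if vals.size == 0 or np.isnan(vals).all():
        return float("nan")
    return float(np.nanmean(vals))


def rank_inverse_normal(values, tie_rule: str = "average") -> np.ndarray:
    """Map values to standard-normal scores via their (mid)ranks.

    A value with midrank r among n maps to ``Phi^{-1}(r / (n + 1))``; the
    offset keeps the extreme scores finite.  Ties share one score and the
    map is order-preserving.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector with at least 2 values")
    if np.isnan(x).any():
        raise ValueError("missing values must be removed before ranking")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: no ranking possible")
    r = rankdata(x, method=tie_rule)
    return norm.ppf(r / (len(x) + 1.0))


def sum_diff(x, y):
    """Sum and difference traits: S = y + x, D = y - x (elementwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pre and post vectors must have the same length")
    return y + x, y - x


def adjust_covariates(t, covariates) -> np.ndarray:
    """OLS residuals of ``t`` on intercept + covariate columns.

    ``covariates`` is a DataFrame (or dict of vectors); a rank-deficient
    design raises an error naming the first column that is collinear with
    the preceding ones.
    """
    t = np.asarray(t, dtype=float)
    cov = pd.DataFrame(covariates)
    if len(cov) != len(t):
        raise ValueError("covariate rows must match trait length")
    names = list(cov.columns)
    X = np.column_stack([np.ones(len(t))] + [cov[c].to_numpy(float) for c in names])
    # incremental rank check pins down the offending column
    rank = 1
    for j, name in enumerate(names, start=2):
        new_rank = np.linalg.matrix_rank(X[:, :j])
        if new_rank < rank + 1:
            raise ValueError(
                f"design is rank-deficient: column {name!r} is collinear "
                "with the intercept/preceding covariates"
            )
        rank = new_rank
    beta, *_ = np.linalg.lstsq(X, t, rcond=None)
    return t - X @ beta


def normalize_dataset(
    study: StudyDataset | pd.DataFrame,
    dataset_id: str | None = None,
) -> NormalizedTraits:
    """Run the four-step pipeline on one dataset's phenotype table.

    Accepts a :class:`StudyDataset` or a bare phenotype DataFrame with
    columns ``pre``, ``post``, ``bmi``, ``age``, ``sex``, ``smoking``.
    Individuals missing any phenotype or covariate are dropped before step
    1 (the OLS step requires complete cases).
    """
    if isinstance(study, StudyDataset):
        pheno = study.pheno
        dataset_id = dataset_id or study.study_id
    else:
        pheno = study
        dataset_id = dataset_id or "dataset"
    cols = ["pre", "post", "bmi", "age", "sex", "smoking"]
    missing = [c for c in cols if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    complete = pheno[cols].notna().all(axis=1)
    ph = pheno.loc[complete, cols]
    if len(ph) < 3:
        raise ValueError("fewer than 3 complete cases in dataset")

    x = rank_inverse_normal(ph["pre"].to_numpy(float))
    y = rank_inverse_normal(ph["post"].to_numpy(float))
    s, d = sum_diff(x, y)

    cov = pd.DataFrame(
        {
            "log_bmi": np.log(ph["bmi"].to_numpy(float)),
            "age": ph["age"].to_numpy(float),
            "sex": ph["sex"].to_numpy(float),
            "smoking": ph["smoking"].to_numpy(float),
        }
    )
    s_res = adjust_covariates(s, cov)
    d_res = adjust_covariates(d, cov)

    s_final = rank_inverse_normal(s_res)
    d_final = rank_inverse_normal(d_res)
    corr = float(np.corrcoef(s_final, d_final)[0, 1])
    return NormalizedTraits(
        dataset_id=dataset_id,
        S=s_final,
        D=d_final,
        ids=ph.index.to_numpy(),
        corr_sd=corr,
    )
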