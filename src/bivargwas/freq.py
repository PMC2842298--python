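"""Frequentist companion scan: additive-model OLS p-values, genomic-control
inflation factor, and QQ-plot coordinates.

The association regression has no covariates: covariate effects were already
removed during phenotype normalization, so the test is a simple regression
of the normalized trait on dosage with an intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FreqResult",
    "lm_pvalue",
    "lm_pvalues_matrix",
    "genomic_control_lambda",
    "qq_points",
]

#: Exact median of the chi-squared distribution with 1 df.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class FreqResult:
    """Slope, standard error and two-sided p-value of one additive test."""

    beta: float
    se: float
    p: float

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.p)


def lm_pvalues_matrix(t, G):
    """Vectorized OLS of a trait on each column of a dosage matrix.

    Returns ``(beta, se, p)`` arrays; two-sided p-values come from the t
    reference distribution with n - 2 degrees of freedom.  Constant
    (monomorphic) columns yield NaN in all three outputs.
    """
    t = np.asarray(t, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n = len(t)
    if n < 3:
        raise ValueError("need n >= 3")
    if G.shape[0] != n:
        raise ValueError("trait and genotype lengths differ")
    tc = t - t.mean()
    Gc = G - G.mean(axis=0)
    sgg = np.einsum("ij,ij->j", Gc, Gc)
    sgt = tc @ Gc
    tss = float(tc @ tc)
    ok = sgg > 0
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    p = np.full(G.shape[1], np.nan)
    beta[ok] = sgt[ok] / sgg[ok]
    rss = tss - beta[ok] ** 2 * sgg[ok]
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / (n - 2)
    se[ok] = np.sqrt(sigma2 / sgg[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    # numerically exact fits give p = 0; keep p in (0, 1]
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    return beta, se, p


def lm_pvalue(t, g) -> FreqResult:
    """Additive-model test of one SNP: slope of trait on intercept+dosage."""
    beta, se, p = lm_pvalues_matrix(t, np.asarray(g, dtype=float))
    return FreqResult(beta=float(beta[0]), se=float(se[0]), p=float(p[0]))


def genomic_control_lambda(pvals) -> float:
    """Genomic-control inflation factor.

    Median of the chi-squared(1 df) statistics implied by the p-values,
    divided by the null median (~0.4549).  Values near 1 indicate no
    systematic inflation.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        warnings.warn(
            f"genomic-control lambda computed from only {len(p)} p-values",
            stacklevel=2,
        )
    if len(p) == 0:
        raise ValueError("no finite p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_points(pvals):
    """(expected, observed) -log10 p coordinates, both ascending.

    Expected quantiles are ``-log10((i - 0.5) / N)`` for i = 1..N; a
    uniform p-value sample falls on the identity line.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no p-values supplied")
    n = len(p)
    expected = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))
    observed = np.sort(-np.log10(p))
    return expected, observed
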