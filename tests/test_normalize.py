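import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from bivargwas.normalize import (
    adjust_covariates,
    average_repeats,
    normalize_dataset,
    rank_inverse_normal,
    sum_diff,
)

from conftest import make_pheno


@pytest.mark.parametrize(
    "visits, expected",
    [((212.0, 212.0), 212.0), ((150.0,), 150.0), ((100.0, 110.0), 105.0)],
)
def test_average_repeats(visits, expected):
    assert average_repeats(visits) == pytest.approx(expected)


def test_average_repeats_handles_missing():
    assert average_repeats((np.nan, 120.0)) == pytest.approx(120.0)
    assert np.isnan(average_repeats((np.nan, np.nan)))


def test_rank_inverse_normal_quantiles():
    # midrank r maps to the normal quantile at r/(n+1)
    got = rank_inverse_normal([5.0, 2.0, 9.0])
    expected = norm.ppf(np.array([2, 1, 3]) / 4.0)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert got[0] == pytest.approx(0.0, abs=1e-12)
    assert got[2] == pytest.approx(0.6744897501960817, abs=1e-9)


def test_rank_inverse_normal_median_and_ties():
    x = np.array([3.0, 1.0, 7.0, 5.0, 4.0])
    assert rank_inverse_normal(x)[np.argsort(x)[2]] == pytest.approx(0.0)
    scores = rank_inverse_normal([1.0, 2.0, 2.0, 5.0])
    assert scores[1] == scores[2]  # tied values share one score


def test_rank_inverse_normal_rejects_degenerate():
    with pytest.raises(ValueError):
        rank_inverse_normal([4.0, 4.0, 4.0])
    with pytest.raises(ValueError):
        rank_inverse_normal([1.0])


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    st.lists(
        st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=60, unique=True
    )
)
def test_rank_inverse_normal_monotone_and_idempotent(values):
    x = np.asarray(values)
    scores = rank_inverse_normal(x)
    order = np.argsort(x)
    assert (np.diff(scores[order]) > 0).all()
    # applying the transform to its own output preserves the scores
    np.testing.assert_allclose(rank_inverse_normal(scores), scores, atol=1e-12)


def test_sum_diff_roundtrip(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    s, d = sum_diff(x, y)
    np.testing.assert_allclose(s, y + x)
    np.testing.assert_allclose(d, y - x)
    np.testing.assert_allclose((s - d) / 2.0, x)
    np.testing.assert_allclose((s + d) / 2.0, y)
    _, d0 = sum_diff(x, x)
    assert np.all(d0 == 0)
    with pytest.raises(ValueError):
        sum_diff(x, y[:10])


def test_adjust_covariates_matches_ols_oracle(rng):
    n = 80
    cov = pd.DataFrame(
        {
            "log_bmi": rng.normal(3.3, 0.2, n),
            "age": rng.normal(60, 9, n),
            "sex": rng.binomial(1, 0.5, n).astype(float),
            "smoking": rng.binomial(1, 0.2, n).astype(float),
        }
    )
    t = rng.normal(size=n) + 0.4 * cov["age"].to_numpy() / 10
    resid = adjust_covariates(t, cov)

    import statsmodels.api as sm

    X = sm.add_constant(cov.to_numpy())
    oracle = sm.OLS(t, X).fit().resid
    np.testing.assert_allclose(resid, oracle, atol=1e-10)
    # residuals orthogonal to every design column
    for col in cov.columns:
        assert abs(resid @ cov[col].to_numpy()) < 1e-8
    assert abs(resid.sum()) < 1e-8


def test_adjust_covariates_perfect_fit_and_collinearity(rng):
    n = 50
    cov = pd.DataFrame(
        {"age": rng.normal(60, 9, n), "sex": rng.binomial(1, 0.5, n).astype(float)}
    )
    t = 2.0 + 0.1 * cov["age"].to_numpy() - 0.5 * cov["sex"].to_numpy()
    np.testing.assert_allclose(adjust_covariates(t, cov), 0.0, atol=1e-10)

    cov["age_copy"] = cov["age"] * 2.0
    with pytest.raises(ValueError, match="age_copy"):
        adjust_covariates(t, cov)


def test_normalize_dataset_construction_and_rank_invariance(rng):
    pheno = make_pheno(151, rng)
    out = normalize_dataset(pheno, "a")
    n = len(out)
    # final S and D are rank-inverse-normal scores by construction
    expected = np.sort(norm.ppf(np.arange(1, n + 1) / (n + 1.0)))
    np.testing.assert_allclose(np.sort(out.S), expected, atol=1e-12)
    np.testing.assert_allclose(np.sort(out.D), expected, atol=1e-12)
    assert abs(out.corr_sd) < 0.2

    # strictly monotone transforms of the raw values change nothing
    transformed = pheno.copy()
    transformed["pre"] = np.exp(1.3 + 2.0 * np.log(pheno["pre"]))
    transformed["post"] = pheno["post"] ** 3
    out2 = normalize_dataset(transformed, "b")
    np.testing.assert_array_equal(out.S, out2.S)
    np.testing.assert_array_equal(out.D, out2.D)


def test_normalize_dataset_cross_dataset_identity(rng):
    # equal-n datasets share the same multiset of scores regardless of
    # raw-scale location/scale differences
    a = normalize_dataset(make_pheno(200, rng, m_pre=5.3, m_post=5.0), "a")
    b = normalize_dataset(
        make_pheno(200, rng, m_pre=5.5, m_post=5.2, scale=0.3), "b"
    )
    np.testing.assert_allclose(np.sort(a.S), np.sort(b.S), atol=1e-12)
    np.testing.assert_allclose(np.sort(a.D), np.sort(b.D), atol=1e-12)


def test_normalize_dataset_drops_incomplete(rng):
    pheno = make_pheno(60, rng)
    pheno.iloc[3, pheno.columns.get_loc("bmi")] = np.nan
    pheno.iloc[7, pheno.columns.get_loc("pre")] = np.nan
    out = normalize_dataset(pheno, "a")
    assert len(out) == 58
    assert pheno.index[3] not in out.ids and pheno.index[7] not in out.ids
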