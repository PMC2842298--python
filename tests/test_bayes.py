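import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bivargwas import bayes

T8 = np.array([-1.2, 0.3, 0.5, -0.7, 1.1, 0.2, -0.4, 0.8])
G8 = np.array([0, 1, 2, 0, 1, 1, 0, 2], dtype=float)
H8 = (G8 == 1).astype(float)


def _random_instance(rng):
    n = int(rng.integers(8, 51))
    g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
    while np.ptp(g) == 0:
        g = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
    h = (g == 1).astype(float)
    sa = float(rng.choice(bayes.DEFAULT_SIGMA_GRID))
    t = rng.normal(size=n) + rng.normal(0, sa) * g + rng.normal(0, sa / 4) * h
    return t, g, h, sa


def test_bf_single_degenerate_cases():
    # zero prior mass on any effect: the models coincide
    assert bayes.bf_single(T8, G8, H8, 0.0, 0.0) == pytest.approx(0.0)
    # monomorphic SNP: centered design is all zero
    assert bayes.bf_single(T8, np.full(8, 2.0), np.zeros(8), 0.1, 0.025) == (
        pytest.approx(0.0)
    )
    with pytest.raises(ValueError):
        bayes.bf_single(T8[:2], G8[:2], None, 0.1, 0.025)
    with pytest.raises(ValueError):
        bayes.bf_single(np.r_[T8[:-1], np.nan], G8, H8, 0.1, 0.025)


def test_bf_single_matches_numeric_oracle_worked_example():
    cf = bayes.bf_single(T8, G8, H8, sigma_a=0.1, sigma_d=0.025)
    oracle = bayes.bf_numeric_oracle(T8, G8, H8, sigma_a=0.1, sigma_d=0.025)
    assert cf == pytest.approx(oracle, rel=1e-6)


def test_bf_numeric_oracle_contract(rng):
    # flat-intercept prior: adding a constant to the trait changes nothing
    a = bayes.bf_numeric_oracle(T8, G8, H8, 0.1, 0.025)
    b = bayes.bf_numeric_oracle(T8 + 37.0, G8, H8, 0.1, 0.025)
    assert a == pytest.approx(b, rel=1e-9)
    assert bayes.bf_numeric_oracle(T8, G8, H8, 0.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        bayes.bf_numeric_oracle(np.zeros(60), np.zeros(60))


def test_bf_averaged_grid_behaviour():
    one = bayes.bf_averaged(T8, G8, H8, sigma_grid=(0.1,))
    assert one == pytest.approx(bayes.bf_single(T8, G8, H8, 0.1, 0.025))
    per = [
        bayes.bf_single(T8, G8, H8, sa, sa * 0.25)
        for sa in bayes.DEFAULT_SIGMA_GRID
    ]
    avg = bayes.bf_averaged(T8, G8, H8)
    assert min(per) <= avg <= max(per)
    # equals the linear-scale mean of the per-grid-point oracle values
    oracle_per = [
        bayes.bf_numeric_oracle(T8, G8, H8, sa, sa * 0.25)
        for sa in bayes.DEFAULT_SIGMA_GRID
    ]
    expected = np.log10(np.mean(10.0 ** np.asarray(oracle_per)))
    assert avg == pytest.approx(expected, rel=1e-6)
    with pytest.raises(ValueError):
        bayes.bf_averaged(T8, G8, H8, sigma_grid=())


def test_sufficient_stats_additivity_and_reconstruction(rng):
    t, g, h, sa = _random_instance(rng)
    k = len(t) // 2
    s1 = bayes.dataset_sufficient_stats(t[:k], g[:k], h[:k])
    s2 = bayes.dataset_sufficient_stats(t[k:], g[k:], h[k:])
    whole = bayes.dataset_sufficient_stats(t, g, h)
    total = s1 + s2
    for f in ("n", "st", "stt", "sg", "sgg", "sgt", "sh", "shh", "sgh", "sht"):
        np.testing.assert_allclose(getattr(total, f), getattr(whole, f), rtol=1e-12)
    # BF from stats reproduces the direct computation
    assert bayes.log10_bf_from_stats(whole, sa, sa / 4) == pytest.approx(
        bayes.bf_single(t, g, h, sa, sa / 4), rel=1e-12
    )


def test_bf_combined_equals_pooled(rng):
    # fixed-effects pooling of sufficient statistics is exactly the BF of
    # the concatenated individuals
    parts, ts, gs, hs = [], [], [], []
    for _ in range(3):
        t, g, h, _ = _random_instance(rng)
        parts.append(bayes.dataset_sufficient_stats(t, g, h))
        ts.append(t), gs.append(g), hs.append(h)
    pooled = bayes.bf_single(
        np.concatenate(ts), np.concatenate(gs), np.concatenate(hs), 0.15, 0.0375
    )
    combined = bayes.bf_combined(parts, 0.15, 0.0375)
    assert combined == pytest.approx(pooled, rel=1e-10)
    # single dataset and permutation invariance
    assert bayes.bf_combined([parts[0]], 0.15, 0.0375) == (
        bayes.log10_bf_from_stats(parts[0], 0.15, 0.0375)
    )
    assert bayes.bf_combined(parts[::-1], 0.15, 0.0375) == combined
    with pytest.raises(ValueError):
        bayes.bf_combined([], 0.1, 0.025)


@settings(derandomize=True, deadline=None, max_examples=30)
@given(st.integers(0, 10_000), st.floats(-50, 50, allow_nan=False))
def test_bf_invariances(seed, shift):
    rng = np.random.default_rng(seed)
    t, g, h, sa = _random_instance(rng)
    base = bayes.bf_single(t, g, h, sa, sa / 4)
    # location shift of the trait (flat intercept prior)
    assert bayes.bf_single(t + shift, g, h, sa, sa / 4) == pytest.approx(
        base, abs=1e-9
    )
    # allele relabeling: g -> 2 - g, heterozygosity unchanged
    assert bayes.bf_single(t, 2.0 - g, h, sa, sa / 4) == pytest.approx(
        base, abs=1e-9
    )


def test_null_expected_bf_is_one(rng):
    # E[BF] = 1 under the null; Monte-Carlo check at sampling tolerance
    n, reps, sa = 50, 4000, 0.1
    g = rng.binomial(2, 0.3, size=(n, reps)).astype(float)
    t = rng.normal(size=(n, reps))
    vals = np.empty(reps)
    for j in range(reps):
        stats = bayes.dataset_sufficient_stats(t[:, j], g[:, j])
        vals[j] = bayes.log10_bf_from_stats(stats, sa, 0.0)
    bf = 10.0 ** vals
    sem = bf.std(ddof=1) / np.sqrt(reps)
    assert abs(bf.mean() - 1.0) < 4.0 * sem
    # under the null log10 BF concentrates at/below zero
    assert np.median(vals) < 0.0


def test_model_posteriors_no_evidence_returns_priors():
    mp = bayes.model_posteriors(0.0, 0.0)
    np.testing.assert_allclose(mp.posteriors, bayes.DEFAULT_PRIORS, rtol=1e-12)
    assert mp.response_prob == pytest.approx(1e-5, rel=1e-9)


def test_model_posteriors_worked_example():
    mp = bayes.model_posteriors(np.log10(1e6), np.log10(10.0))
    np.testing.assert_allclose(
        mp.posteriors, [0.0055, 0.497, 5.5e-8, 0.497], rtol=5e-3
    )
    assert mp.response_prob == pytest.approx(0.497, rel=5e-3)
    assert mp.posteriors.sum() == pytest.approx(1.0, abs=1e-12)


def test_model_posteriors_rejects_bad_priors():
    with pytest.raises(ValueError):
        bayes.model_posteriors(0.0, 0.0, priors=(0.5, 0.5, 0.5, 0.5))


@settings(derandomize=True, deadline=None, max_examples=40)
@given(st.floats(-30, 30), st.floats(-30, 30))
def test_model_posteriors_normalized(bs, bd):
    mp = bayes.model_posteriors(bs, bd)
    assert mp.posteriors.sum() == pytest.approx(1.0, abs=1e-12)
    assert ((mp.posteriors >= 0) & (mp.posteriors <= 1)).all()


def test_response_probability_cases():
    # published-table worked example: components (0.16, 0.0, 0.07, 0.77)
    mp = bayes.ModelPosterior.from_components([0.16, 0.0, 0.07, 0.77])
    assert bayes.response_probability(mp) == pytest.approx(0.84, abs=1e-9)
    all_s = bayes.ModelPosterior.from_components([0.0, 1.0, 0.0, 0.0])
    assert all_s.response_prob == 0.0


def test_rescale_prior_sensitivity():
    mp = bayes.ModelPosterior.from_components([0.16, 0.0, 0.07, 0.77])
    same = bayes.rescale_prior_sensitivity(mp, 1.0)
    np.testing.assert_allclose(same.posteriors, mp.posteriors)
    skeptical = bayes.rescale_prior_sensitivity(mp, 0.2)
    assert skeptical.response_prob == pytest.approx(0.512, abs=0.005)
    generous = bayes.rescale_prior_sensitivity(mp, 4.0)
    assert generous.response_prob > 0.95
    with pytest.raises(ValueError):
        bayes.rescale_prior_sensitivity(mp, 0.0)


def _columnwise_stats(t, g, h):
    """SuffStats with per-SNP trait vectors (one trait column per SNP)."""
    return bayes.SuffStats(
        n=float(t.shape[0]),
        st=t.sum(axis=0),
        stt=np.einsum("ij,ij->j", t, t),
        sg=g.sum(axis=0),
        sgg=np.einsum("ij,ij->j", g, g),
        sgt=np.einsum("ij,ij->j", t, g),
        sh=h.sum(axis=0),
        shh=np.einsum("ij,ij->j", h, h),
        sgh=np.einsum("ij,ij->j", g, h),
        sht=np.einsum("ij,ij->j", t, h),
    )


def test_posterior_calibration_under_matched_generative_model(rng):
    # when effects are drawn from the analysis prior, posterior response
    # probabilities are calibrated: among SNPs assigned response_prob in a
    # band, the realized fraction of true response SNPs falls in the band
    n, m = 1200, 40_000
    priors = np.array([0.90, 0.05, 0.01, 0.04])
    grid = np.asarray(bayes.DEFAULT_SIGMA_GRID)
    labels = rng.choice(4, size=m, p=priors)
    sa = rng.choice(grid, size=m)
    bf_s = np.empty(m)
    bf_d = np.empty(m)
    for lo in range(0, m, 5000):
        sl = slice(lo, lo + 5000)
        g = rng.binomial(2, 0.3, size=(n, 5000)).astype(float)
        h = (g == 1.0).astype(float)
        a_s = rng.normal(0, sa[sl]) * np.isin(labels[sl], [1, 3])
        d_s = rng.normal(0, sa[sl] / 4) * np.isin(labels[sl], [1, 3])
        a_d = rng.normal(0, sa[sl]) * np.isin(labels[sl], [2, 3])
        d_d = rng.normal(0, sa[sl] / 4) * np.isin(labels[sl], [2, 3])
        t_s = g * a_s + h * d_s + rng.normal(size=(n, 5000))
        t_d = g * a_d + h * d_d + rng.normal(size=(n, 5000))
        bf_s[sl] = bayes.log10_bf_grid_average(_columnwise_stats(t_s, g, h))
        bf_d[sl] = bayes.log10_bf_grid_average(_columnwise_stats(t_d, g, h))
    from bivargwas.bayes import model_posteriors_array

    post = model_posteriors_array(bf_s, bf_d, priors)
    resp = post[:, 2] + post[:, 3]
    band = (resp >= 0.7) & (resp <= 0.9)
    assert band.sum() >= 30
    realized = np.isin(labels[band], [2, 3]).mean()
    se = np.sqrt(0.8 * 0.2 / band.sum())
    assert 0.7 - 4.0 * se <= realized <= 0.9 + 4.0 * se
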