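# Methods

## Model and rationale

For each participant there are two measurements of a quantitative phenotype
on a common normalized scale: baseline X and on-treatment Y. Working with
the reparameterization S = Y + X, D = Y − X is convenient because (i) a
SNP is a *response* association exactly when it is associated with D, and
(ii) S and D are (near-)uncorrelated after normalization. Most SNPs that
genuinely affect response are expected to affect S too (a SNP associated
with D but not S would need exactly opposite effects on X and Y), so the
model space is the four hypotheses

| model | meaning | Bayes factor | prior |
|---|---|---|---|
| H0   | no association            | 1            | 1 − 10⁻⁴    |
| HS   | S only (treatment-independent) | BF_S    | 0.9 × 10⁻⁴  |
| HD   | D only                    | BF_D         | 0.01 × 10⁻⁴ |
| HS+D | both                      | BF_S · BF_D  | 0.09 × 10⁻⁴ |

The product form for HS+D assumes independence of S and D. The priors put
10⁻⁴ on any association per SNP and 10⁻⁵ on a response association, and are
deliberately less skeptical about a D association accompanied by an S
association. Posterior model probabilities are the normalized
prior-weighted BFs; the *response probability* is P(HD) + P(HS+D). Because
posteriors that are not near 0/1 are sensitive to these priors,
`rescale_prior_sensitivity` implements the exact Bayes-rule update for
changing the response prior by a factor without re-touching data.

## Bayes factor

Single-SNP model for a normalized trait t: t = μ + a·g + d·h + ε with
ε ~ N(0, σ²), g the dosage (expected minor-allele count in [0, 2]) and h
the heterozygote probability. Priors: a ~ N(0, σa²σ²), d ~ N(0, σd²σ²),
p(μ) ∝ 1, p(σ²) ∝ 1/σ². The improper μ and σ² priors are shared with the
null model (μ only), so the BF is well-defined:

BF = |I + V WᵀW|^(−1/2) · (RSS_B/TSS)^(−(n−1)/2),

W the centered [g, h] columns, V = diag(σa², σd²), TSS the centered trait
sum of squares and RSS_B = TSS − t_cᵀW(WᵀW + V⁻¹)⁻¹Wᵀt_c. Setting
σd = σa/4 puts most prior weight on near-additive effects while allowing
dominance. σa is averaged (equal weights, linear BF scale) over
{0.05, 0.075, 0.1, 0.125, 0.15, 0.2, 0.4}, spanning effects from ~0.05 to
~0.4 phenotypic SD per allele. All BF arithmetic is in log10 space
(log-sum-exp for the grid average): genome-wide scans produce BFs spanning
hundreds of orders of magnitude.

The closed form is treated as unverified until proven: `bf_numeric_oracle`
integrates the same posterior over (a, d, σ²) by tensor Gauss–Legendre
quadrature (outer grid in log σ², inner box centered on the exponent's
minimizer, with node *placement* informed by the integrand's curvature but
the *value* a plain quadrature sum of the raw integrand), and the test
suite requires 1e−5 relative agreement on random small instances. The
oracle is restricted to n ≤ 50 by design.

Degenerate inputs: σa = σd = 0 or a SNP monomorphic in all datasets give
BF = 1 (the models coincide); such SNPs are flagged, their posteriors set
to the priors and their frequentist result reported missing. When a
genotype source provides dosages only, h is unavailable; the model then
degrades to additive-only (h ≡ 0). This loses the (small, σd = σa/4)
dominance component — dosages alone do not identify heterozygosity — and
is the package-wide behaviour for dosage-only VCF/BIMBAM input without
het-probability data.

## Fixed-effects multi-study combination

One shared genetic effect across studies is assumed. Per-dataset raw sums
(n, Σt, Σt², and the cross-products of [1, g, h] with themselves and t)
are pooled component-wise and the closed form applied to the pooled sums;
this equals the BF of the concatenated per-dataset-normalized individuals
*exactly* (tested to 1e−10 relative), and is not the product of per-study
BFs, which would encode independent per-study effects. Heterogeneity of
true effects across studies mis-specifies the alternative (losing power)
but leaves the null untouched, so it cannot create false positives.

## Normalization

The four-step pipeline (rank-inverse-normal pre and post → S, D →
covariate residualization → rank-inverse-normal again) is applied per
dataset. The rank transform maps midrank r of n to Φ⁻¹(r/(n+1)); the
r/(n+1) offset keeps extremes finite and midranks give ties one shared
score (the exact tie/offset convention is a package choice — any
order-preserving variant gives the same downstream ranks for untied data).
Covariates are log(BMI), age, sex (0/1), smoking (0/1); individuals
missing any field are dropped from that dataset before step 1. The
re-transform after residualization restores an exact standard-normal
marginal; the induced correlation between final S and D is reported
(`NormalizedTraits.corr_sd`) but not forced to zero — on simulated data it
is negligibly small. Consequences verified by tests: invariance to any
strictly increasing transform of raw pre or post values, and identical
score multisets across equal-n datasets.

## Frequentist companion

Additive-model OLS of the normalized trait on intercept + dosage, no
covariates (they were removed during normalization). Two-sided p-values
use the exact t distribution with n − 2 df. Genomic control
λ = median(χ²₁ quantiles of the p-values) / 0.45494 (the exact χ²₁
median); QQ coordinates are −log10 p against −log10((i − 0.5)/N).

## Synthetic data generator

Emulates the study conditions the analysis assumes, with defaults fixed at
the combined-trial scale: three studies of 592/1,364/1,976 individuals
(total 3,932); per-study raw-scale affine parameters (m_pre, m_post, s)
matched to the trials' total-cholesterol means (~212→153, 215→174,
245→174 mg/dL, log-scale sd 0.12–0.17); covariates age ~ N(60, 10²),
BMI log-normal around 28 kg/m², sex ~ Bern(0.7), smoking ~ Bern(0.15).
Genotypes are Binomial(2, MAF) under HWE with per-study MAF jitter
(sd 0.01, clipped to [0.01, 0.5]); imputation noise is a deterministic
blend dosage = (1−r)·genotype + r·2·MAF — the simplest model that
preserves E[dosage] while attenuating information, standing in for
posterior-mean genotypes from imputation (no posterior triples, no LD).
Latent traits are S* = Σβg + covariate terms + ε, D* likewise, scaled to
unit variance; effect sizes are specified as variance explained (the one
currency the analysis reports; e.g. a response SNP "explaining 1% of
var(D)") and converted to coefficients via the theoretical dosage
variance. Raw phenotypes are X_raw = exp(m_pre + s(S*−D*)/2),
Y_raw = exp(m_post + s(S*+D*)/2): log-normal by construction, so the rank
normalization behaves like a log transform, and strictly monotone in the
latent values, so the affine parameters are provably irrelevant after
normalization.

What the generator does *not* emulate — LD between SNPs, population
stratification and relatedness, case/control ascertainment within a trial,
per-visit measurement replicates (beyond `average_repeats`), genotyping
batch effects — bounds what passing tests show: calibration and recovery
hold for independent SNPs in homogeneous samples; confounding by structure
is out of scope by design (the real analysis handles it by checking λ and
PCA robustness, mirrored here only through λ on null scans).

## ANCOVA bias module

Simulates a SNP with the *same* effect β on X and Y (so D is effect-free)
with residual corr(X, Y) = ρ: X = βg + e_x, Y = βg + e_y. The ANCOVA test
(genotype coefficient in Y ~ 1 + g + X) rejects far above its nominal
level whenever β ≠ 0 and ρ < 1, because conditioning on X makes g
informative about Y through the shared effect; the difference test
((Y−X) ~ 1 + g) stays calibrated. Defaults — n = 1,000, MAF 0.3, β sized
to explain 2% of var(X), ρ = 0.5, 2,000 replicates — make the inflation
unmistakable at desk scale (rejection ~0.7 at α = 0.05). Inflation grows
with |β| and with decreasing ρ (tested on a small grid).

## Numerical and design choices

* Problem sizes in the test suite: the null-calibration check scans 10⁵
  SNPs at n = 4,000 in blocks of 5,000 (vectorized sufficient statistics);
  parameter recovery uses 50 single-SNP replicates at n = 3,932; the
  oracle comparison uses 100 instances at n ≤ 50.
* Region reporting: SNPs on one chromosome are chain-merged within a 500 kb
  window (a parameter — "region" has no canonical definition);
  representative = smallest P(H0), ties by p-value on the relevant trait
  (p_D when the row's evidence favors response, else p_S), then position.
* Overall MAF is the sample-size-weighted mean of per-dataset MAFs.
* Dosage files are coded on the minor allele; a column whose dosage
  frequency exceeds 0.5 is flipped on read and logged.
* All simulation randomness flows from a single integer seed expanded per
  study/block via `numpy` SeedSequence; same seed ⇒ bit-identical output.
* Traits are scanned independently per phenotype; there is no cross-trait
  model, no multi-SNP model, and no random-effects heterogeneity model.

## Known limitations

The dominance column is silently absent for dosage-only input (additive
model only). The posterior calibration property holds when the generative
effect-size distribution matches the analysis prior; on real data the
posteriors inherit any prior mis-specification, which is why the
prior-sensitivity rescaling is part of the reporting surface. The
generator's independence assumptions mean multiple-SNP regions in its
output reflect chance, not LD.
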