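# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `twinace`, in the spirit of a package
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Twin likelihoods

All model fitting is Gaussian maximum likelihood on per-group sufficient
statistics (pair count, mean vector, ML covariance matrix). Because the
likelihood of a multivariate-normal model depends on data only through these
statistics, repeated fits — multi-start, bootstrap resamples, calibration
replicates — cost microseconds to milliseconds regardless of cohort size.

**Univariate ACE.** Pairs (y₁, y₂) per zygosity group are bivariate normal
with a single mean μ equated across twin order and zygosity, total variance
V = a² + c² + e², and co-twin covariance r_A·a² + c² with genetic
relatedness r_A = 1 (MZ) or 0.5 (DZ). Variance components are parameterized
as squared path coefficients, giving implicit non-negativity; boundary
solutions are reported as exact zeros, and no negative-c² "broad"
parameterization is offered. The saturated reference frees 5 moments per
group (2 means, 2 variances, 1 covariance), so with two groups the ACE model
has df = 10 − 4 = 6 and AE/CE have df = 7. Means equation is deliberate: it
reproduces this df accounting, which the package treats as part of the model
definition.

**Bivariate correlated factors.** Each pair contributes (X₁, Y₁, X₂, Y₂).
Within-twin cross-trait covariance is a_X a_Y·rG + c_X c_Y·rC + e_X e_Y·rE;
cross-twin cross-trait covariance keeps the C term, multiplies the G term by
r_A, and drops E. The correlated-factors parameterization (6 paths + 3
correlations bounded in [−1, 1]) is used rather than a Cholesky because the
correlations are the quantities reported. When a component's variance is
near zero in either trait (< 0.001 on unit-variance scale) its correlation
is reported as NaN with a flag — undefined, not zero. A linear moment solve
(Falconer per trait; G = 2(c_MZ − c_DZ) etc. for the cross-trait products)
provides both the starting values and an exact oracle on population moments.

**Common pathway.** Ten-variate pairs; one latent factor with unit variance
and latent ACE shares (parameterized as normalized squares, so the shares sum
to 1 by construction) feeds the five traits through free loadings λᵢ, plus
trait-specific ACE residuals. Identification: latent variance 1, λ₁ ≥ 0.
The free-parameter count is 27 (5 means, 5 loadings, 2 effective latent
shares, 15 specific paths) against 130 saturated moments (two groups), so
df = 103. Optional pruning bootstraps the raw loading and specific-a/c paths
(warm-started single-start refits), sets paths whose 95% CI covers zero to
zero, and refits once — single pass, to avoid order-dependent iterative
pruning.

**Sex limitation.** Five groups; per-sex means, variances and A, C, E paths;
a sex-specific additive component A′ correlating 1 / 0.5 / 0 across MZ,
same-sex DZ and opposite-sex co-twins. The DZos cross-covariance
½a_f a_m + c_f c_m is the only moment separating A′ from A, which makes the
"A′ in both sexes" variant weakly identified: within-sex data constrain only
a² + a′², and the single DZos moment constrains the product a_f a_m. The
package therefore defaults to estimating A′ in one sex at a time and flags
the both-sex variant. The general-vs-common-effects comparison is an
ordinary ML likelihood-ratio test, labelled "unscaled LRT": the
Satorra–Bentler scaling used with robust estimators corrects for
non-normality that does not arise here, where the inputs are residualized
continuous scores fitted by plain ML.

## Preprocessing

Fixed order, logged in every report: reverse-code → EM-impute → clip to
[1, 5] → log10 → moment screen (|skew| ≥ 3, |excess kurtosis| ≥ 10, report
only) → residualize → factor scores and composites. The order follows the
usual narrative sequence of questionnaire handling; imputation before
transformation keeps the EM model on the (roughly interval) response scale,
and clipping before log10 is forced by the positivity requirement —
continuous imputed values are retained, not rounded.

EM imputation treats individuals (not pairs) as rows, ignoring family
clustering, as is standard for questionnaire imputation at ~1.5%
missingness; the observed-data log-likelihood is tracked and must be
non-decreasing. Singular observed-block covariances are ridge-regularized
(1e-8) with a warning.

Factor analysis is per-scale (five separate one-factor ML fits), not a joint
five-factor model; the fit is delegated to scikit-learn's `FactorAnalysis`
behind the package's own surface, with uniquenesses floored at 0.005
(Heywood bound) and the loading-sum sign convention. Scores are Bartlett
(conditionally unbiased: regression of scores on the true factor has unit
slope); they are left on the Bartlett scale, and the twin models estimate a
free total variance, so no standardization convention is imposed between
stages. Composites are item-set means z-standardized with the n−1 SD
convention. Sex analyses residualize on age only — wired into the pipeline
(`scores_age_only.csv`) rather than left to user discipline.

## Synthetic cohorts

The generator states a world and sticks to it. Defaults: 3,248 MZ and 6,314
DZ pairs split MZf 2098 / MZm 1150 / DZf 2040 / DZm 1117 / DZos 3157 —
matching the reference totals exactly, female-leaning in the ratio of the
reference sample (8,415:4,609), with opposite-sex pairs about half of the DZ
group as in population twin registries; ages uniform on 18–49 shared within
pair; 1.5% responses missing completely at random; five 5-item scales with
item loadings averaging 0.7 and thresholds placing 60/20/10/5/5% of mass on
categories 1–5 (adversity items are strongly right-skewed); seven items
reverse-coded; the emotional-abuse and both neglect scales marked
family-specific. Default trait architecture: a² = 0.5, c² = 0.2, e² = 0.3
with cross-trait rG = 0.43, rC = 0.55, rE = 0.13 (the field-typical
magnitudes for co-occurring maltreatment).

Liabilities are sums of A/C/E factors with the appropriate co-twin
correlations (shared/unique decomposition per factor; Cholesky of rG/rC/rE
across traits), so marginal trait variance is exactly 1. Named RNG streams
(liabilities / measurement / missingness / ages, derived from one seed by
stage-name CRC) make each stage's draws independent of the others' draw
counts. Identical seed and config give byte-identical cohorts.

What the generator does **not** emulate: non-MCAR missingness, assortative
mating, dominance, gene–environment interaction, age trends in exposure,
zygosity misclassification, and ordinal floor effects beyond what the
thresholds imply. A green recovery test therefore establishes that the
estimators recover the stated linear-Gaussian-threshold world — not that
they would be unbiased under those unmodelled features. In particular,
factor scores carry measurement error that loads on E, so item-based
pipelines attenuate a² and c² relative to the generating liabilities; tests
that need exact model-level truth use the retained continuous liabilities,
which is why the simulator exposes them.

## Numerical choices

- Optimizer: L-BFGS-B with tight tolerances (ftol ≈ 1e-14) from a
  Falconer/moment-solve start plus jittered multi-starts under a fixed
  sub-seed, then a Nelder–Mead polish for headline fits; bootstrap refits are
  warm-started single-start without polish.
- Bounds: a, c ≥ 0; e ≥ 1e-4 (keeps Σ positive definite); correlations in
  [−0.9999, 0.9999]; common-pathway specific-e paths ≥ 1e-3.
- LRTs for dropping variance components use the naive χ² reference, not the
  ½χ²₀ + ½χ²₁ boundary mixture — conservative (null rejection below
  nominal), matching common practice, and noted in every run manifest.
- RMSEA: √(max(0, (χ² − df)/(df(n − 1)))) with the 90% CI from inverting the
  noncentral χ² CDF at 5%/95% (bounds 0 when the central CDF is already
  below the level); fit labels: upper CI < 0.06 excellent, < 0.08 mediocre.
- AIC = −2lnL + 2k; BIC = −2lnL + k·ln(n). The sample size for BIC and
  RMSEA is the number of **pairs** in the analysis group — a convention,
  logged in the manifest.
- Bootstrap CIs default to normal-theory (estimate ± 1.96·bootstrap SD,
  i.e. "CIs based on bootstrapped standard errors"); the percentile variant
  is available. Resampling is stratified within zygosity group; resamples
  where the statistic fails are dropped and counted, with an error above
  10% failures.
- Model selection: candidates are submodels not rejected against ACE at
  α = 0.05; winner is lowest AIC, ties broken toward fewer parameters.
- CI-overlap comparison: no overlap or CIs just touching counts as a
  significant difference; the effect size is the raw difference of
  estimates.

## Calibration choices in the test suite

Simulation sizes for the calibration checks were fixed up front: bootstrap
coverage uses 200 replicate cohorts of 1,000 + 1,000 MZ/DZ pairs with
B = 200 resamples; the sex-limitation null LRT uses 200 replicate five-group
cohorts of 500 pairs per group with the default single-sex A′ configuration
(the boundary mixture puts roughly half the null mass at zero, so the naive
test rejects below the nominal 5%); the ACE-vs-AE LRT under AE truth uses
200 replicates of 1,000 + 1,000 pairs.

## Known limitations

- No FIML for partially observed pairs: imputation precedes modelling.
- No ordinal-liability (threshold/polychoric) models; transformed items are
  treated as continuous.
- No dominance (ADE), independent-pathway, multi-factor common-pathway, or
  scalar sex-limitation variants; no sex-limited C′.
- The both-sex A′ model is estimable but near-singular; its per-sex A′
  split should not be interpreted, only the joint improvement in fit.
- Double-entered cross-twin correlations are descriptive; inference uses
  pair counts and the likelihood machinery, never double-entered n.
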