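# twinace

Classical twin-design variance decomposition for retrospective questionnaire
phenotypes, built around the analysis pipeline of a registry-scale twin study
of childhood adversity: ordinal items → factor scores → ACE models →
multivariate and sex-limitation models, with a synthetic twin-cohort
generator standing in for confidential cohort data.

## The models

For a trait measured on both members of monozygotic (MZ) and dizygotic (DZ)
twin pairs, phenotypic variance is decomposed into additive genetic (A),
shared environmental (C) and unique environmental (E) components. Each pair
(y₁, y₂) is bivariate normal with a common mean μ, total variance
V = a² + c² + e², and co-twin covariance

    cov_MZ = a² + c²        cov_DZ = ½a² + c²

reflecting genetic relatedness 1 (MZ) vs 0.5 (DZ) and fully shared family
environment. Fitting is by maximum likelihood on per-group sufficient
statistics; submodels (AE, CE, E) are screened by likelihood-ratio test
against ACE and ranked by AIC; 95% CIs come from a stratified family
bootstrap. On exact population moments the ML solution equals the Falconer
estimators a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ, e² = 1 − r_MZ, which the
test suite verifies to 1e-6.

Beyond the univariate model:

- **Bivariate correlated factors** — cross-trait covariance decomposes as
  a_X a_Y·rG + c_X c_Y·rC + e_X e_Y·rE, estimating the genetic (rG), shared-
  (rC) and unique-environmental (rE) correlations between two traits.
- **Common pathway** — one latent liability with its own ACE decomposition
  (latent variance fixed to 1) feeds all five traits through loadings λᵢ,
  with trait-specific ACE residuals.
- **Sex limitation** — five zygosity groups (MZf, MZm, DZf, DZm, DZos); a
  sex-specific additive component A′ is uncorrelated across opposite-sex
  co-twins, so the DZos cross-covariance ½a_f a_m + c_f c_m is what
  separates it from ordinary A. General (A′ free) vs common-effects
  (A′ = 0) models are compared by an unscaled LRT.

The preprocessing stage mirrors standard questionnaire practice: reverse-code
→ EM imputation under a multivariate normal model → clip to the 1–5 scale →
log10 → skew/kurtosis screen → residualize on age and sex (age only for sex
analyses) → per-scale maximum-likelihood single-factor analysis with
Bartlett factor scores, plus family-specific / family-unspecific composite
z-scores.

The synthetic cohort generator draws trait liabilities with any ACE
architecture (including common-pathway and sex-limitation generative modes),
discretizes them to 5-point ordinal items through configurable loadings and
thresholds, and knocks out responses completely at random. Generating
liabilities are retained so model-level properties can be tested without
measurement error.

## Worked example

```python
from twinace import (simulate_cohort, preprocess_cohort, pairs_by_group,
                     submodel_search)

cohort = simulate_cohort(seed=4)          # 3,248 MZ + 6,314 DZ pairs
scores, report = preprocess_cohort(cohort)
pairs = pairs_by_group(scores, "emotional_abuse")
search = submodel_search(pairs, seed=0)
vc = search.winner
print(search.best, round(vc.a2, 2), round(vc.c2, 2), round(vc.e2, 2))
```

Running `python examples/04_univariate_ace.py` (an AE-generated cohort,
a² = 0.6, c² = 0) prints the full comparison table and selects AE:

```
  ACE  -2lnL =  57631.58  chi2(6) =    8.04  RMSEA = 0.006 ...  LRT p vs ACE = 1.000
  AE   -2lnL =  57631.58  chi2(7) =    8.04  RMSEA = 0.004 ...  LRT p vs ACE = 0.951
  CE   -2lnL =  57786.49  chi2(7) =  162.95  RMSEA = 0.048 ...  LRT p vs ACE = 0.000
  E    -2lnL =  58750.47  chi2(8) = 1126.94  RMSEA = 0.121 ...  LRT p vs ACE = 0.000
selected: AE
  a2 = 0.44 [0.42, 0.47]
  c2 = 0.00 [0.00, 0.00]
  e2 = 0.56 [0.53, 0.58]
```

The heritability estimate (0.44) sits below the generating 0.6 because
factor scores carry measurement error, which loads on E — see
`docs/methods.md` for what green tests do and do not establish. The other
`examples/` scripts cover simulation, preprocessing, twin correlations,
genetic correlations, the common-pathway model, sex limitation and the full
config-driven pipeline.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch on the default
synthetic cohort — simulation, preprocessing, twin correlations, univariate
model search with 1,000-resample bootstrap CIs, bivariate correlations, the
common-pathway fit and the sex-limitation analyses — writing intermediate
outputs under `scratch/` and the summary JSON to `--out`.
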