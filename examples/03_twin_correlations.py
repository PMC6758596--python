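"""Twin correlations by zygosity: the phenotypic fingerprint of heritability.

Cross-twin within-trait correlations larger in MZ than DZ pairs indicate
additive-genetic influence; DZ correlations above half the MZ value indicate
shared environment; MZ correlations below 1 indicate unique environment
(plus measurement error).
"""

from twinace import TRAIT_NAMES, preprocess_cohort, simulate_cohort, twin_correlations

cohort = simulate_cohort(
    seed=3, n_per_group={"MZf": 2000, "MZm": 1200, "DZf": 1800, "DZm": 1200,
                         "DZos": 1800},
)
scores, _ = preprocess_cohort(cohort)
corr = twin_correlations(scores, list(TRAIT_NAMES))

ct = corr[corr.kind == "cross_twin_within_trait"].pivot(
    index="trait_1", columns="group", values="r")
print("cross-twin within-trait correlations (double-entered):")
print(ct.round(3).to_string())
print(f"\nmean rMZ = {ct['MZ'].mean():.2f}, mean rDZ = {ct['DZ'].mean():.2f}")
print("rMZ > rDZ signals genetic influence; generating truth has "
      "a2 = 0.5, c2 = 0.2 before measurement attenuation")

cc = corr[corr.kind == "cross_twin_cross_trait"].groupby("group")["r"].mean()
print(f"mean cross-twin cross-trait: MZ = {cc['MZ']:.2f}, "
      f"DZ = {cc['DZ']:.2f} (MZ > DZ: shared etiology across traits)")
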