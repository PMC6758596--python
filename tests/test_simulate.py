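"""Synthetic twin-cohort generator: moment structure, items, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from twinace import (
    CommonPathwayTruth,
    MeasurementModel,
    SexLimTruth,
    TraitArchitecture,
    inject_missingness,
    liabilities_to_items,
    simulate_cohort,
    simulate_liabilities,
)

from conftest import liability_pairs


def _cross_twin_r(pairs):
    return {g: np.corrcoef(a[:, 0], a[:, 1])[0, 1] for g, a in pairs.items()}


class TestLiabilities:
    def test_no_familial_variance_gives_zero_cross_twin_correlation(self):
        arch = TraitArchitecture(a2=[0.0], c2=[0.0], e2=[1.0])
        r = _cross_twin_r(
            liability_pairs(arch, {"MZf": 10000, "DZf": 10000}, seed=1)
        )
        assert abs(r["MZ"]) < 0.05 and abs(r["DZ"]) < 0.05

    def test_expected_twin_correlations(self, simple_arch):
        # rMZ = a2 + c2 = 0.8, rDZ = a2/2 + c2 = 0.5
        r = _cross_twin_r(
            liability_pairs(simple_arch, {"MZf": 50000, "DZf": 50000}, seed=2)
        )
        assert r["MZ"] == pytest.approx(0.8, abs=0.01)
        assert r["DZ"] == pytest.approx(0.5, abs=0.01)

    def test_default_cohort_composition(self):
        cohort = simulate_cohort(seed=3, missing_rate=0.0)
        counts = cohort.wide["zygosity"].value_counts()
        assert counts["MZf"] + counts["MZm"] == 3248
        assert counts["DZf"] + counts["DZm"] + counts["DZos"] == 6314

    def test_marginal_variance_is_one(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 30000, "DZf": 30000}, seed=4)
        for arr in pairs.values():
            assert arr.var() == pytest.approx(1.0, abs=0.02)

    def test_cross_trait_covariance_recovers_architecture(self):
        # within-twin cov(i,j) = ai aj rG + ci cj rC + ei ej rE
        n = 5
        rG = np.full((n, n), 0.43); np.fill_diagonal(rG, 1)
        rC = np.full((n, n), 0.55); np.fill_diagonal(rC, 1)
        rE = np.full((n, n), 0.13); np.fill_diagonal(rE, 1)
        arch = TraitArchitecture(
            a2=np.full(n, 0.5), c2=np.full(n, 0.2), e2=np.full(n, 0.3),
            rG=rG, rC=rC, rE=rE,
        )
        liab, _ = simulate_liabilities(arch, {"DZf": 50000}, seed=5)
        X = liab[:, 0, :]
        expected = (
            0.5 * 0.43 + 0.2 * 0.55 + 0.3 * 0.13
        )
        emp = np.cov(X, rowvar=False)
        off = emp[np.triu_indices(n, 1)]
        assert np.allclose(off, expected, atol=0.02)

    def test_non_psd_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="rG"):
            TraitArchitecture(a2=[0.5] * 3, c2=[0.2] * 3, e2=[0.3] * 3, rG=bad)

    def test_determinism_same_seed_identical_cohort(self):
        n = {"MZf": 200, "DZm": 200, "DZos": 100}
        c1 = simulate_cohort(seed=42, n_per_group=n)
        c2 = simulate_cohort(seed=42, n_per_group=n)
        pd.testing.assert_frame_equal(c1.wide, c2.wide)
        c3 = simulate_cohort(seed=43, n_per_group=n)
        assert not c1.wide.equals(c3.wide)

    def test_common_pathway_mode_matches_direct_covariance_mode(self):
        # CP truth implies within-twin cov(i,j) = lam_i lam_j; build the
        # equivalent direct architecture and compare 2x2-block covariances
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])
        cp = CommonPathwayTruth(
            loadings=lam, latent_a2=0.5, latent_c2=0.2, latent_e2=0.3,
            specific_a2=0.0, specific_c2=0.0, specific_e2=1 - lam**2,
        )
        arch_cp = TraitArchitecture(
            a2=np.full(5, 0.5), c2=np.full(5, 0.2), e2=np.full(5, 0.3),
            common_pathway=cp,
        )
        # direct equivalent: per trait a2 = 0.5 lam^2, c2 = 0.2 lam^2,
        # e2 = 0.3 lam^2 + (1 - lam^2); rX_ij such that products match
        a2 = 0.5 * lam**2
        c2 = 0.2 * lam**2
        e2 = 1 - a2 - c2

        def corr_from(prod_comp, comp_var):
            R = np.ones((5, 5))
            for i in range(5):
                for j in range(5):
                    if i != j:
                        R[i, j] = prod_comp[i, j] / np.sqrt(
                            comp_var[i] * comp_var[j]
                        )
            return R

        rG = corr_from(0.5 * np.outer(lam, lam), a2)
        rC = corr_from(0.2 * np.outer(lam, lam), c2)
        rE = corr_from(0.3 * np.outer(lam, lam), e2)
        arch_direct = TraitArchitecture(a2=a2, c2=c2, e2=e2, rG=rG, rC=rC, rE=rE)

        n = {"MZf": 30000, "DZf": 30000}
        for seed, (ac, ad) in ((6, (arch_cp, arch_direct)),):
            Lc, mc = simulate_liabilities(ac, n, seed)
            Ld, md = simulate_liabilities(ad, n, seed + 1)
            for zyg in ("MZf", "DZf"):
                Xc = Lc[(mc.zygosity == zyg).to_numpy()]
                Xd = Ld[(md.zygosity == zyg).to_numpy()]
                Cc = np.cov(
                    np.concatenate([Xc[:, 0], Xc[:, 1]], axis=1), rowvar=False
                )
                Cd = np.cov(
                    np.concatenate([Xd[:, 0], Xd[:, 1]], axis=1), rowvar=False
                )
                assert np.abs(Cc - Cd).max() < 0.04

    def test_dzos_sex_specific_genes_uncorrelated(self):
        # only A' varies -> DZos co-twins uncorrelated, same-sex DZ r = 0.5*ap2
        sl = SexLimTruth(
            a2_f=0.0, c2_f=0.0, e2_f=0.2, ap2_f=0.8,
            a2_m=0.0, c2_m=0.0, e2_m=0.2, ap2_m=0.8,
        )
        arch = TraitArchitecture(a2=[0.0], c2=[0.0], e2=[1.0], sexlim=sl)
        pairs = liability_pairs(
            arch, {"DZf": 10000, "DZos": 10000}, seed=7, pooled=False
        )
        r = _cross_twin_r(pairs)
        assert abs(r["DZos"]) < 0.05
        assert r["DZf"] == pytest.approx(0.4, abs=0.05)

    def test_ages_shared_within_pair_and_in_range(self):
        cohort = simulate_cohort(
            seed=8, n_per_group={"MZf": 500}, age_range=(18, 43)
        )
        ages = cohort.wide["age"]
        assert ages.between(18, 43).all()


class TestItems:
    def test_noiseless_items_are_step_function_of_liability(self):
        mm = MeasurementModel(
            loadings=np.array([1.0]),
            thresholds=np.array([[-1.0, 0.0, 1.0, 2.0]]),
            reverse_coded=frozenset(), family_specific=frozenset(),
            items_per_trait=1,
        )
        liab = np.array([[-2.0], [-0.5], [0.5], [1.5], [2.5]])
        items = liabilities_to_items(liab, mm, seed=0)
        assert items.ravel().tolist() == [1, 2, 3, 4, 5]

    def test_category_proportions_match_thresholds(self):
        thr = sps.norm.ppf([0.6, 0.8, 0.9, 0.95])
        mm = MeasurementModel(
            loadings=np.array([0.7]), thresholds=thr[None, :],
            reverse_coded=frozenset(), family_specific=frozenset(),
            items_per_trait=1,
        )
        rng = np.random.default_rng(0)
        liab = rng.standard_normal((200000, 1))
        items = liabilities_to_items(liab, mm, seed=1).ravel()
        props = np.bincount(items.astype(int), minlength=6)[1:] / len(items)
        assert np.allclose(props, [0.6, 0.2, 0.1, 0.05, 0.05], atol=0.01)

    def test_reverse_coded_items_emit_six_minus_category(self):
        thr = np.array([[-1.0, 0.0, 1.0, 2.0]])
        base = dict(loadings=np.array([1.0]), thresholds=thr,
                    family_specific=frozenset(), items_per_trait=1)
        fwd = MeasurementModel(reverse_coded=frozenset(), **base)
        rev = MeasurementModel(reverse_coded=frozenset({0}), **base)
        liab = np.array([[-0.5]])  # raw category 2
        assert liabilities_to_items(liab, fwd, seed=0).item() == 2
        assert liabilities_to_items(liab, rev, seed=0).item() == 4

    def test_trait_count_mismatch_rejected(self):
        mm = MeasurementModel.default()
        with pytest.raises(ValueError, match="trait count"):
            liabilities_to_items(np.zeros((10, 2, 3)), mm, seed=0)


class TestMissingness:
    def test_rate_zero_is_identity(self):
        x = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(inject_missingness(x, 0.0, seed=0), x)

    def test_empirical_rate_near_nominal(self):
        x = np.ones((9562 * 2, 25))
        out = inject_missingness(x, 0.015, seed=1)
        assert np.isnan(out).mean() == pytest.approx(0.015, abs=0.002)

    def test_missing_count_within_binomial_interval(self):
        x = np.ones((100, 10))
        out = inject_missingness(x, 0.5, seed=2)
        assert 466 <= np.isnan(out).sum() <= 534  # Binomial(1000, .5) 99% CI

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            inject_missingness(np.ones((2, 2)), 1.0, seed=0)


class TestRoundTrip:
    def test_csv_round_trip_preserves_data(self, tmp_path):
        cohort = simulate_cohort(
            seed=9, n_per_group={"MZf": 50, "DZos": 50}
        )
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = cohort.from_csv(path)
        pd.testing.assert_frame_equal(
            cohort.wide, back.wide, check_dtype=False
        )
        assert back.arch is not None and back.mm is not None
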