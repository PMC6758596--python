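"""Univariate ACE fitting: oracle equivalence, df accounting, model search,
bootstrap, fit indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinace import (
    TraitArchitecture,
    bootstrap_ci,
    ci_overlap_compare,
    fit_ace,
    fit_saturated,
    information_criteria,
    rmsea,
    stats_from_moments,
    submodel_search,
)
from twinace.univariate import ace_statistic, falconer, pair_stats

from conftest import liability_pairs


class TestFitACE:
    def test_no_familial_resemblance_all_unique_environment(self):
        vc, _ = fit_ace(stats_from_moments(0.0, 0.0))
        assert vc.a2 == pytest.approx(0.0, abs=1e-6)
        assert vc.c2 == pytest.approx(0.0, abs=1e-6)
        assert vc.e2 == pytest.approx(1.0, abs=1e-6)

    def test_falconer_oracle_on_exact_moments(self):
        # a2 = 2(rMZ-rDZ), c2 = 2rDZ-rMZ, e2 = 1-rMZ
        vc, _ = fit_ace(stats_from_moments(0.8, 0.5))
        assert vc.a2 == pytest.approx(0.6, abs=1e-6)
        assert vc.c2 == pytest.approx(0.2, abs=1e-6)
        assert vc.e2 == pytest.approx(0.2, abs=1e-6)

    def test_parameter_recovery_from_simulated_pairs(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 5000, "DZf": 5000}, seed=11)
        vc, _ = fit_ace(pairs)
        assert vc.a2 == pytest.approx(0.5, abs=0.04)
        assert vc.c2 == pytest.approx(0.2, abs=0.04)
        assert vc.e2 == pytest.approx(0.3, abs=0.04)

    def test_rmz_below_rdz_forces_zero_heritability(self):
        vc, _ = fit_ace(stats_from_moments(0.2, 0.4))
        assert vc.a2 == pytest.approx(0.0, abs=1e-6)

    def test_standardized_components_scale_invariant(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 2000, "DZf": 2000}, seed=12)
        vc1, _ = fit_ace(pairs)
        vc2, _ = fit_ace({g: 7.3 * a for g, a in pairs.items()})
        assert vc2.a2 == pytest.approx(vc1.a2, abs=1e-6)
        assert vc2.total_variance == pytest.approx(
            7.3**2 * vc1.total_variance, rel=1e-5)

    def test_likelihood_nesting_chain(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 1000, "DZf": 1000}, seed=13)
        m2 = {m: fit_ace(pairs, model=m)[1].minus2ll
              for m in ("ACE", "AE", "CE", "E")}
        sat = fit_saturated(pairs).minus2ll
        assert m2["E"] >= m2["AE"] - 1e-8
        assert m2["AE"] >= m2["ACE"] - 1e-8
        assert m2["ACE"] >= sat - 1e-8

    @given(st.floats(0.05, 0.85), st.floats(0.0, 0.1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_components_sum_to_one(self, rmz_extra, rdz_gap):
        rdz = 0.05 + rdz_gap
        rmz = min(rdz + rmz_extra, 0.95)
        vc, _ = fit_ace(stats_from_moments(rmz, rdz))
        assert vc.a2 + vc.c2 + vc.e2 == pytest.approx(1.0, abs=1e-10)
        assert min(vc.a2, vc.c2, vc.e2) >= 0

    def test_e_only_boundary_flagged(self):
        vc, _ = fit_ace(stats_from_moments(0.6, 0.3), model="E")
        assert any("boundary" in f for f in vc.flags)


class TestDfAccounting:
    def test_saturated_model_frees_ten_moments_in_two_groups(self):
        fit = fit_saturated(stats_from_moments(0.8, 0.5))
        assert fit.k_params == 10

    def test_ae_df_seven_ace_df_six(self):
        stats = stats_from_moments(0.6, 0.3)
        assert fit_ace(stats, model="AE")[1].df == 7
        assert fit_ace(stats, model="ACE")[1].df == 6

    def test_dropped_components_are_exact_zero(self):
        vc, _ = fit_ace(stats_from_moments(0.6, 0.3), model="AE")
        assert vc.c2 == 0.0 and vc.paths["c"] == 0.0


class TestFitIndices:
    def test_rmsea_zero_when_chi2_equals_df(self):
        point, ci, _ = rmsea(7.0, 7, 1000)
        assert point == 0.0 and ci[0] == 0.0

    def test_rmsea_direct_formula(self):
        point, _, _ = rmsea(14.0, 7, 1000)
        assert point == pytest.approx(np.sqrt(7 / (7 * 999)), abs=1e-12)

    def test_rmsea_labels_follow_thresholds(self):
        # construct chi2 values whose upper CI lands in each band
        _, ci, label = rmsea(7.0, 7, 2000)
        assert ci[1] < 0.06 and label == "excellent"
        _, ci, label = rmsea(100.0, 7, 2000)
        assert ci[1] >= 0.08 and label == "poor"
        _, ci, label = rmsea(60.0, 7, 2000)
        assert label == "mediocre"

    def test_rmsea_undefined_for_zero_df(self):
        with pytest.raises(ValueError):
            rmsea(5.0, 0, 100)

    def test_aic_difference_is_twice_parameter_gap(self):
        a3, _ = information_criteria(100.0, 3, 500)
        a4, _ = information_criteria(100.0, 4, 500)
        assert a4 - a3 == pytest.approx(2.0)

    def test_zero_parameters_ic_equal_m2ll(self):
        aic, bic = information_criteria(123.4, 0, 50)
        assert aic == bic == 123.4

    def test_bic_log_n(self):
        _, bic = information_criteria(100.0, 4, int(round(np.e**2)))
        assert bic == pytest.approx(100 + 4 * np.log(round(np.e**2)))


class TestSubmodelSearch:
    def test_ae_truth_selects_ae(self):
        arch = TraitArchitecture(a2=[0.6], c2=[0.0], e2=[0.4])
        pairs = liability_pairs(arch, {"MZf": 10000, "DZf": 10000}, seed=14)
        res = submodel_search(pairs)
        assert res.best == "AE"

    def test_null_truth_selects_e_most_of_the_time(self):
        arch = TraitArchitecture(a2=[0.0], c2=[0.0], e2=[1.0])
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            pairs = liability_pairs(
                arch, {"MZf": 10000, "DZf": 10000}, seed=100 + rep)
            if submodel_search(pairs).best == "E":
                wins += 1
        assert wins >= int(0.9 * n_rep) - 1  # ~binomial slack at 20 reps

    def test_rmz_below_rdz_winner_has_zero_a2(self):
        res = submodel_search(stats_from_moments(0.2, 0.4))
        assert res.winner.a2 == pytest.approx(0.0, abs=1e-6)


class TestBootstrap:
    def test_constant_statistic_zero_width(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 200, "DZf": 200}, seed=15)
        ci = bootstrap_ci(pairs, lambda p: 3.0, B=100, seed=0)
        assert ci.lower.item() == ci.upper.item() == 3.0

    def test_same_seed_identical_bounds(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 500, "DZf": 500}, seed=16)
        stat = ace_statistic()
        c1 = bootstrap_ci(pairs, ace_statistic(), B=100, seed=3)
        c2 = bootstrap_ci(pairs, ace_statistic(), B=100, seed=3)
        assert c1.lower.item() == c2.lower.item()
        assert c1.upper.item() == c2.upper.item()

    def test_percentile_option(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 500, "DZf": 500}, seed=17)
        ci = bootstrap_ci(pairs, ace_statistic(), B=200, seed=4,
                          method="percentile")
        assert ci.lower.item() < ci.estimate.item() < ci.upper.item()

    def test_failure_fraction_guard(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 100, "DZf": 100}, seed=18)
        calls = {"n": 0}

        def flaky(p):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match="resamples"):
            bootstrap_ci(pairs, flaky, B=100, seed=5)


class TestCIOverlap:
    @pytest.mark.parametrize(
        "ci1,ci2,expect",
        [
            ((0.1, 0.3), (0.3, 0.5), True),  # just touching counts
            ((0.1, 0.35), (0.3, 0.5), False),  # overlap
            ((0.1, 0.2), (0.4, 0.5), True),  # clear separation
        ],
    )
    def test_overlap_rule(self, ci1, ci2, expect):
        sig, es = ci_overlap_compare(np.mean(ci1), ci1, np.mean(ci2), ci2)
        assert sig is expect

    def test_identical_estimates_not_significant(self):
        sig, es = ci_overlap_compare(0.3, (0.2, 0.4), 0.3, (0.2, 0.4))
        assert not sig and es == 0.0

    def test_effect_size_is_raw_difference(self):
        _, es = ci_overlap_compare(0.6, (0.5, 0.7), 0.2, (0.1, 0.3))
        assert es == pytest.approx(0.4)


class TestFalconerHelper:
    def test_matches_closed_form_on_moments(self):
        a2, c2, e2, V = falconer(stats_from_moments(0.8, 0.5, V=2.0))
        assert (a2, c2, e2) == pytest.approx((0.6, 0.2, 0.2))
        assert V == pytest.approx(2.0)

    def test_pair_stats_shapes(self, ace_arch):
        pairs = liability_pairs(ace_arch, {"MZf": 50, "DZf": 60}, seed=19)
        stats = pair_stats(pairs)
        assert stats["MZ"].n == 50 and stats["DZ"].n == 60
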