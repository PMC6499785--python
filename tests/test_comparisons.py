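"""Two-sample tests, effect sizes, and their summary/raw equivalence."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from senet.comparisons import (cohens_d, compare_site_groups, group_ttest,
                               levene_test, mann_whitney_u)
from senet.ecology import TransectRecord
from senet.synthetic import EcoEffect, SiteScenario, gen_species_traits, \
    gen_transects


class TestGroupTtest:
    def test_welch_with_zero_variance_group(self):
        gc = group_ttest((3, 1021.75, 83.04), (2, 951.77, 0.0), variant="welch")
        assert round(gc.t, 2) == 1.46
        assert gc.df == pytest.approx(2.0)

    def test_welch_fractional_df(self):
        gc = group_ttest((26, 29.98, 14.69), (45, 32.68, 9.30), variant="welch")
        assert round(gc.t, 2) == -0.84
        assert round(gc.df, 1) == 36.8

    def test_identical_groups_zero_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        gc = group_ttest(x, x, variant="pooled")
        assert gc.t == 0 and gc.cohens_d == 0

    def test_summary_equals_raw_sample_path(self, rng):
        x1 = rng.normal(0, 1, 20)
        x2 = rng.normal(0.5, 2, 15)
        for variant in ("pooled", "welch"):
            raw = group_ttest(x1, x2, variant=variant)
            summ = group_ttest((20, x1.mean(), x1.std(ddof=1)),
                               (15, x2.mean(), x2.std(ddof=1)),
                               variant=variant)
            assert raw.t == pytest.approx(summ.t, rel=1e-12)
            assert raw.df == pytest.approx(summ.df, rel=1e-12)
            assert raw.cohens_d == pytest.approx(summ.cohens_d, rel=1e-12)

    def test_agrees_with_scipy(self, rng):
        x1 = rng.normal(0, 1, 12)
        x2 = rng.normal(1, 3, 18)
        for variant, equal_var in (("pooled", True), ("welch", False)):
            gc = group_ttest(x1, x2, variant=variant)
            ref = sps.ttest_ind(x1, x2, equal_var=equal_var)
            assert gc.t == pytest.approx(ref.statistic, rel=1e-10)
            assert gc.p == pytest.approx(ref.pvalue, rel=1e-10)
            assert gc.df == pytest.approx(ref.df, rel=1e-10)

    def test_welch_df_never_exceeds_pooled(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 30, 2)
            s1, s2 = rng.uniform(0.1, 5, 2)
            w = group_ttest((n1, 0.0, s1), (n2, 1.0, s2), variant="welch")
            assert w.df <= n1 + n2 - 2 + 1e-9
        eq = group_ttest((10, 0.0, 2.0), (10, 1.0, 2.0), variant="welch")
        assert eq.df == pytest.approx(18.0)

    def test_zero_variance_equal_means_undefined(self):
        gc = group_ttest((5, 1.0, 0.0), (5, 1.0, 0.0), variant="pooled")
        assert np.isnan(gc.t) and "undefined" in gc.note

    def test_auto_requires_raw_for_summaries(self):
        with pytest.raises(ValueError, match="auto"):
            group_ttest((5, 1.0, 1.0), (5, 2.0, 1.0), variant="auto")

    def test_one_sided_direction(self, rng):
        x1 = rng.normal(2, 1, 30)
        x2 = rng.normal(0, 1, 30)
        greater = group_ttest(x1, x2, variant="pooled", sidedness="greater")
        less = group_ttest(x1, x2, variant="pooled", sidedness="less")
        assert greater.p < 0.01 and less.p > 0.99


class TestCohensD:
    def test_pooled_sd_weighting(self):
        d, _ = cohens_d((3, 1021.75, 83.04), (2, 951.77, 0.0))
        assert round(d, 2) == 1.03

    def test_sign_matches_mean_difference(self):
        d, _ = cohens_d((3, 119.0, 98.88), (2, 153.5, 21.92))
        assert round(d, 2) == -0.42

    def test_equal_means_zero(self):
        d, ci = cohens_d((10, 5.0, 1.0), (10, 5.0, 2.0))
        assert d == 0 and ci[0] < 0 < ci[1]

    def test_ci_brackets_estimate(self, rng):
        x1 = rng.normal(1, 1, 25)
        x2 = rng.normal(0, 1, 25)
        d, (lo, hi) = cohens_d(x1, x2, ci_level=0.90)
        assert lo < d < hi
        d2, (lo2, hi2) = cohens_d(x1, x2, ci_level=0.99)
        assert lo2 < lo and hi2 > hi  # wider at higher confidence


class TestLevene:
    def test_duplicate_groups_zero(self):
        x = [1.0, 2.0, 5.0, 9.0]
        vt = levene_test([x, list(x)])
        assert vt.W == pytest.approx(0.0)

    def test_detects_unequal_variance(self, rng):
        x1 = rng.normal(0, 1, 200)
        x2 = rng.normal(0, 3, 200)
        assert levene_test([x1, x2]).p < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            levene_test([[1.0, 2.0], [3.0]])

    def test_df_reported(self, rng):
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        vt = levene_test(groups)
        assert vt.df == (2, 27)


class TestMannWhitney:
    def test_identical_multisets_half_product(self):
        rt = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert rt.U == 4.5

    def test_complete_separation_full_product(self):
        rt = mann_whitney_u([10, 11, 12], [1, 2])
        assert rt.U == 6  # n1 * n2

    def test_u_within_bounds(self, rng):
        x1, x2 = rng.normal(0, 1, 8), rng.normal(0, 1, 9)
        rt = mann_whitney_u(x1, x2)
        assert 0 <= rt.U <= 72

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_p_equals_enumeration(self, seed):
        """Small-sample one-sided p matches exhaustive permutation."""
        rng = np.random.default_rng(seed)
        x1 = rng.normal(0, 1, 4)
        x2 = rng.normal(0.8, 1, 5)
        rt = mann_whitney_u(x1, x2, alternative="greater")
        assert rt.method == "exact"
        pooled = np.concatenate([x1, x2])
        ranks = sps.rankdata(pooled)
        n1 = len(x1)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = []
        for pos in itertools.combinations(range(len(pooled)), n1):
            r = ranks[list(pos)].sum() - n1 * (n1 + 1) / 2
            us.append(r)
        p_enum = np.mean(np.array(us) >= u_obs)
        assert rt.p == pytest.approx(p_enum, abs=1e-12)


class TestCompareSiteGroups:
    def _transects(self, seed, eco_a, eco_b):
        traits = gen_species_traits(20, np.random.default_rng(0))
        mk = lambda sid, eco, s: gen_transects(
            SiteScenario(site_id=sid, n_fishers=80, seed=s, eco=eco,
                         n_transects=6, n_species=20),
            traits, np.random.default_rng(s))
        by_site = {"P": mk("P", eco_a, seed), "Q": mk("Q", eco_b, seed + 1)}
        return by_site, traits

    def test_true_effect_detected(self):
        hi = EcoEffect(650.0, 120.0, 24.0, 3.0)
        lo = EcoEffect(380.0, 120.0, 17.0, 3.0)
        by_site, traits = self._transects(1, hi, lo)
        gc = compare_site_groups(by_site, {"P"}, "biomass", traits)
        assert gc.t > 0 and gc.p < 0.05

    def test_null_effect_d_centred_on_zero(self):
        eco = EcoEffect(500.0, 150.0, 20.0, 3.0)
        ds = []
        for rep in range(25):
            by_site, traits = self._transects(100 + 2 * rep, eco, eco)
            gc = compare_site_groups(by_site, {"P"}, "biomass", traits)
            ds.append(gc.cohens_d)
        assert abs(np.mean(ds)) < 3 * np.std(ds, ddof=1) / np.sqrt(len(ds)) + 0.2

    def test_single_group_rejected(self):
        eco = EcoEffect(500.0, 150.0, 20.0, 3.0)
        by_site, traits = self._transects(7, eco, eco)
        with pytest.raises(ValueError, match="nonempty"):
            compare_site_groups(by_site, {"P", "Q"}, "biomass", traits)

    def test_unknown_metric_rejected(self):
        eco = EcoEffect(500.0, 150.0, 20.0, 3.0)
        by_site, traits = self._transects(7, eco, eco)
        with pytest.raises(KeyError, match="unknown metric"):
            compare_site_groups(by_site, {"P"}, "shannon", traits)
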