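"""Group statistics: t-test, Cohen's d, Agresti-Caffo, ICC, densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from spinemorph.stats import (DensityRecord, agresti_caffo, cohens_d,
                              compare_cluster_distributions, density_summary,
                              holm_correction, icc_oneway, spine_density,
                              ttest_unpaired)


class TestDensity:
    def test_basic_values(self):
        assert spine_density(10, 20.0) == pytest.approx(0.5)
        assert spine_density(0, 15.0) == 0.0

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            spine_density(5, 0.0)

    def test_group_summary(self):
        records = [DensityRecord(f"c{i}", f"m{i % 2}", "ctrl", 10 + i, 20.0)
                   for i in range(4)]
        records += [DensityRecord("c9", "m9", "occl", 5, 25.0)]
        out = density_summary(records)
        assert out.loc["ctrl", "n_cells"] == 4
        assert out.loc["ctrl", "n_mice"] == 2
        assert out.loc["ctrl", "mean_density"] == pytest.approx(
            np.mean([(10 + i) / 20.0 for i in range(4)]))
        assert out.loc["occl", "mean_density"] == pytest.approx(0.2)


class TestTTest:
    def test_identical_samples(self):
        t, p = ttest_unpaired([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.3, 40)
        t, p = ttest_unpaired(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_hand, rel=1e-12)

    def test_constant_samples_equal_means(self):
        assert ttest_unpaired([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_constant_samples_unequal_means(self):
        with pytest.raises(ValueError):
            ttest_unpaired([1.0, 1.0], [2.0, 2.0])


class TestCohensD:
    def test_identical_samples_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).cohens_d == pytest.approx(0.0)

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 1, 5000), rng.normal(0, 1, 5000)
        es = cohens_d(a, b)
        assert es.cohens_d == pytest.approx(1.0, abs=0.06)
        # bands follow the shifted convention (< 0.2 small), so 1.0 falls
        # in the 0.8-1.2 "very large" band
        assert es.interpretation == "very large"

    def test_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 4.0, 4.5])
        b = np.array([2.0, 3.0, 3.5, 6.0, 7.0])
        pooled = math.sqrt((3 * a.var(ddof=1) + 4 * b.var(ddof=1)) / 7)
        assert cohens_d(a, b).cohens_d == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_interpretation_bands(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 20000)
        assert cohens_d(base + 0.001, base).interpretation == "very small"
        assert cohens_d(base + 0.1, base).interpretation == "small"

    def test_affine_equivariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 50), rng.normal(1, 2, 60)
        d0 = cohens_d(a, b).cohens_d
        d1 = cohens_d(3 * a + 7, 3 * b + 7).cohens_d
        assert d1 == pytest.approx(d0, rel=1e-12)


class TestAgrestiCaffo:
    def test_symmetric_counts(self):
        res = agresti_caffo(5, 10, 5, 10)
        assert res.z == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_antisymmetry(self):
        r1 = agresti_caffo(30, 100, 50, 120)
        r2 = agresti_caffo(50, 120, 30, 100)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_ci_contains_diff_and_matches_statsmodels(self):
        from statsmodels.stats.proportion import confint_proportions_2indep
        res = agresti_caffo(30, 100, 50, 120)
        assert res.ci95[0] <= res.diff <= res.ci95[1]
        lo, hi = confint_proportions_2indep(30, 100, 50, 120,
                                            method="agresti-caffo", compare="diff")
        assert res.ci95[0] == pytest.approx(lo, abs=2e-4)  # 1.96 vs exact quantile
        assert res.ci95[1] == pytest.approx(hi, abs=2e-4)

    def test_adjusted_proportions(self):
        res = agresti_caffo(0, 10, 10, 10)
        assert res.p_tilde_1 == pytest.approx(1 / 12)
        assert res.p_tilde_2 == pytest.approx(11 / 12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            agresti_caffo(11, 10, 1, 10)

    @settings(max_examples=200, derandomize=True)
    @given(n1=st.integers(1, 500), n2=st.integers(1, 500),
           f1=st.floats(0, 1), f2=st.floats(0, 1))
    def test_properties_hold_for_arbitrary_counts(self, n1, n2, f1, f2):
        x1, x2 = round(f1 * n1), round(f2 * n2)
        res = agresti_caffo(x1, n1, x2, n2)
        swapped = agresti_caffo(x2, n2, x1, n1)
        assert 0 < res.p_tilde_1 < 1 and 0 < res.p_tilde_2 < 1
        assert 0 <= res.p_two_sided <= 1
        assert res.ci95[0] <= res.diff <= res.ci95[1]
        assert res.z == pytest.approx(-swapped.z, rel=1e-12, abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 across 10000 replicates."""
        rng = np.random.default_rng(2024)
        n, p0, reps = 200, 0.2, 10000
        x1 = rng.binomial(n, p0, size=reps)
        x2 = rng.binomial(n, p0, size=reps)
        p1, p2 = (x1 + 1) / (n + 2), (x2 + 1) / (n + 2)
        se = np.sqrt(p1 * (1 - p1) / (n + 2) + p2 * (1 - p2) / (n + 2))
        pvals = 2 * norm.sf(np.abs((p1 - p2) / se))
        # spot-check the vectorized replication against the implementation
        spot = agresti_caffo(int(x1[0]), n, int(x2[0]), n)
        assert spot.p_two_sided == pytest.approx(pvals[0])
        rate = (pvals < 0.05).mean()
        assert 0.035 <= rate <= 0.065


class TestClusterDistributions:
    def test_identical_groups_all_null(self):
        labels = np.array([1, 1, 2, 2, 3, 3, 3])
        res = compare_cluster_distributions(labels, labels, k=3)
        assert all(r.p_two_sided == pytest.approx(1.0) for r in res.values())

    def test_composition_matches_direct_call(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 4, 200)
        b = np.concatenate([a, np.ones(50, dtype=int)])
        res = compare_cluster_distributions(a, b, k=3)
        direct = agresti_caffo(int((a == 1).sum()), len(a), int((b == 1).sum()), len(b))
        assert res[1].p_two_sided == pytest.approx(direct.p_two_sided)

    def test_counts_conserve_group_sizes(self):
        rng = np.random.default_rng(5)
        a, b = rng.integers(1, 6, 300), rng.integers(1, 6, 200)
        res = compare_cluster_distributions(a, b, k=5)
        assert sum(r.p_tilde_1 * (len(a) + 2) - 1 for r in res.values()) == pytest.approx(len(a))
        assert sum(r.p_tilde_2 * (len(b) + 2) - 1 for r in res.values()) == pytest.approx(len(b))

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        a = rng.integers(1, 4, 300)
        b = np.concatenate([a, np.ones(80, dtype=int)])
        raw = compare_cluster_distributions(a, b, k=3, holm=False)
        adj = compare_cluster_distributions(a, b, k=3, holm=True)
        for c in raw:
            assert adj[c].p_two_sided >= raw[c].p_two_sided - 1e-12

    def test_holm_formula(self):
        np.testing.assert_allclose(holm_correction([0.01, 0.04, 0.03]),
                                   [0.03, 0.06, 0.06])


class TestICC:
    def test_perfect_grouping(self):
        values = np.repeat([1.0, 5.0, 9.0], 10)
        groups = np.repeat(["a", "b", "c"], 10)
        assert icc_oneway(values, groups).icc >= 0.999

    def test_null_grouping_near_zero(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=600)
        groups = np.repeat([f"g{i}" for i in range(30)], 20)
        assert abs(icc_oneway(values, groups).icc) < 0.05

    def test_variance_component_recovery(self):
        """sigma_b^2 = 3, sigma_w^2 = 1 -> ICC = 0.75."""
        rng = np.random.default_rng(8)
        n_groups, per = 50, 20
        b = rng.normal(0, math.sqrt(3), n_groups)
        values = (b[:, None] + rng.normal(0, 1, (n_groups, per))).ravel()
        groups = np.repeat(np.arange(n_groups), per)
        assert icc_oneway(values, groups).icc == pytest.approx(0.75, abs=0.05)

    def test_matches_pingouin_icc1(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(9)
        values = (rng.normal(0, 1, (6, 8)) + rng.normal(0, 2, 6)[:, None]).ravel()
        groups = np.repeat([f"g{i}" for i in range(6)], 8)
        ours = icc_oneway(values, groups).icc
        df = pd.DataFrame({"targets": groups,
                           "raters": np.tile(np.arange(8), 6),
                           "scores": values})
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type").loc["ICC(1,1)", "ICC"]
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway([1.0, 2.0], ["a", "a"])
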