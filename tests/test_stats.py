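"""Correlation battery, FDR control, group tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from conftest import brute_force_bh, synthetic_cohort_table
from mstmeg import (bh_fdr, chi_square_2x2, compare_correlations,
                    pearson_corr, run_association_battery, two_sample_t,
                    two_sample_t_from_samples)
from mstmeg.stats import metric_column

# the nine whole-sample raw p-values of the band x metric correlation table
WHOLE_SAMPLE_P = [0.048, 0.194, 0.232, 0.011, 0.103, 0.015, 0.184, 0.591, 0.142]
# the eighteen subgroup raw p-values pooled into one family
SUBGROUP_P = [0.023, 0.005, 0.521, 0.034, 0.514, 0.011, 0.455, 0.868, 0.631,
              0.498, 0.246, 0.140, 0.164, 0.108, 0.641, 0.172, 0.149, 0.047]


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r = pearson_corr(x, 2 * x + 1)
        assert r.estimate == pytest.approx(1.0)
        assert r.p_raw < 1e-12

    def test_four_point_hand_value(self):
        # hand computation: cov = 1, var_x = var_y = 5/3 -> rho = 0.6
        r = pearson_corr(np.array([1, 2, 3, 4.0]), np.array([2, 1, 4, 3.0]))
        assert r.estimate == pytest.approx(0.6)

    def test_null_p_values_uniform(self):
        # 1000 independent n=76 replicates; p from t distribution (df 74)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((1000, 76))
        y = rng.standard_normal((1000, 76))
        xs = (x - x.mean(1, keepdims=True))
        ys = (y - y.mean(1, keepdims=True))
        r = (xs * ys).sum(1) / np.sqrt((xs ** 2).sum(1) * (ys ** 2).sum(1))
        t = r * np.sqrt(74 / (1 - r ** 2))
        p = 2 * sps.t.sf(np.abs(t), df=74)
        assert sps.kstest(p, "uniform").pvalue > 0.01
        # spot-check the vectorized replicate against the implementation
        res = pearson_corr(x[0], y[0])
        assert res.estimate == pytest.approx(r[0])
        assert res.p_raw == pytest.approx(p[0])

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestBhFdr:
    def test_whole_sample_family_adjusted_values(self):
        res = bh_fdr(np.array(WHOLE_SAMPLE_P), q=0.1)
        by_p = dict(zip(WHOLE_SAMPLE_P, res.q_adj))
        assert by_p[0.048] == pytest.approx(0.144, abs=5e-4)
        assert by_p[0.232] == pytest.approx(0.261, abs=5e-4)
        assert res.threshold == pytest.approx(0.015)
        assert set(np.array(WHOLE_SAMPLE_P)[res.significant]) == {0.011, 0.015}

    def test_pooled_subgroup_family_threshold(self):
        res = bh_fdr(np.array(SUBGROUP_P), q=0.1)
        assert res.threshold == pytest.approx(0.011)

    def test_single_p_stepup(self):
        res = bh_fdr(np.array([0.05]), q=0.1)
        assert res.q_adj[0] == pytest.approx(0.05)
        assert res.significant[0]
        assert res.threshold == pytest.approx(0.05)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = rng.integers(1, 25)
            # mix of null and signal-like p-values, with ties
            p = np.round(rng.uniform(0, 1, m) ** rng.uniform(0.5, 3), 3)
            res = bh_fdr(p, q=0.1)
            adj, rej, thr = brute_force_bh(p, q=0.1)
            np.testing.assert_allclose(res.q_adj, adj, atol=1e-12)
            np.testing.assert_array_equal(res.significant, rej)
            assert res.threshold == pytest.approx(thr)

    @given(st.integers(0, 10_000))
    def test_adjusted_monotone_in_raw_p(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 12)
        res = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.q_adj[order]) >= -1e-15)
        assert np.all(res.q_adj >= p)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bh_fdr(np.array([]))


class TestGroupTests:
    def test_pooled_t_from_biomarker_summaries(self):
        # group summaries (mean, sd, n) = (390.706, 147.107, 54) vs
        # (359.58, 174.491, 22)
        res = two_sample_t(390.706, 147.107, 54, 359.58, 174.491, 22)
        assert res.estimate == pytest.approx(0.792, abs=5e-4)
        assert res.p_raw == pytest.approx(0.431, abs=5e-3)

    def test_pooled_t_age_summaries(self):
        # recomputation from the rounded printed summaries gives -1.428;
        # the published table prints -1.42
        res = two_sample_t(60.741, 5.779, 54, 62.955, 6.938, 22)
        assert res.estimate == pytest.approx(-1.42, abs=1e-2)

    def test_identical_groups(self):
        res = two_sample_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.estimate == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_matches_direct_pooled_formula(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.3, 1.5, 15)
        res = two_sample_t_from_samples(a, b)
        sp2 = ((19 * a.var(ddof=1) + 14 * b.var(ddof=1)) / 33)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 20 + 1 / 15))
        assert res.estimate == pytest.approx(t, abs=1e-12)

    def test_chi_square_sex_table(self):
        # ((17, 37), (10, 12)): N(ad-bc)^2 / (r1 r2 c1 c2) = 1.3325
        res = chi_square_2x2([[17, 37], [10, 12]])
        assert res.estimate == pytest.approx(1.3325, abs=5e-4)
        assert res.p_raw == pytest.approx(0.248, abs=5e-3)

    def test_chi_square_perfect_independence(self):
        assert chi_square_2x2([[10, 10], [10, 10]]).estimate == 0.0

    def test_chi_square_two_formula_cross_check(self, rng):
        c = rng.integers(1, 50, (2, 2)).astype(float)
        a, b = c[0]
        cc, d = c[1]
        n = c.sum()
        direct = n * (a * d - b * cc) ** 2 / (
            (a + b) * (cc + d) * (a + cc) * (b + d))
        assert chi_square_2x2(c).estimate == pytest.approx(direct, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestCompareCorrelations:
    # printed one-tailed Fisher r-to-z comparisons recomputable from (rho, n)
    @pytest.mark.parametrize("r1,r2,expected", [
        (0.308, 0.152, 0.269),    # theta leaf fraction
        (-0.373, 0.258, 0.007),   # theta diameter
        (0.289, 0.307, 0.471),    # alpha leaf fraction
        (0.067, 0.428, 0.073),    # beta tree hierarchy
    ])
    def test_printed_column_reproduced(self, r1, r2, expected):
        res = compare_correlations(r1, 54, r2, 22)
        assert res.p_raw == pytest.approx(expected, abs=5e-4)

    def test_equal_correlations(self):
        res = compare_correlations(0.3, 30, 0.3, 40)
        assert res.estimate == 0.0
        assert res.p_raw == pytest.approx(0.5)

    def test_swap_symmetry(self):
        a = compare_correlations(-0.373, 54, 0.258, 22)
        b = compare_correlations(0.258, 22, -0.373, 54)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 30, 0.5, 30)


class TestBattery:
    def test_family_sizes(self):
        table = synthetic_cohort_table(0)
        res = run_association_battery(table)
        assert (res["family"] == "whole_sample").sum() == 9
        assert (res["family"] == "subgroup").sum() == 18
        assert (res["family"] == "group_comparison").sum() == 9
        # the two FDR families are corrected separately
        whole = res[res["family"] == "whole_sample"]
        sub = res[res["family"] == "subgroup"]
        assert whole["q_adj"].notna().all() and sub["q_adj"].notna().all()
        assert res.loc[res["family"] == "group_comparison", "q_adj"].isna().all()

    def test_missing_column_named(self):
        table = synthetic_cohort_table(1).drop(columns=["biomarker"])
        with pytest.raises(ValueError, match="biomarker"):
            run_association_battery(table)

    def test_demographic_screens_when_covariates_present(self):
        table = synthetic_cohort_table(2)
        rng = np.random.default_rng(5)
        table["age"] = rng.normal(61, 6, len(table))
        table["education"] = rng.normal(18, 5, len(table))
        table["sex"] = rng.permutation(["M"] * 27 + ["F"] * 49)
        res = run_association_battery(table)
        demo = res[res["family"] == "demographics"]
        assert set(demo["metric"]) == {"age", "education", "biomarker_by_sex",
                                       "sex_by_group"}

    def test_null_family_false_rejection_rate(self):
        # global null: BH at q=0.1 rejects anything in at most ~10% of
        # replicates (binomial 3-sigma margin over 200 replicates)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            table = synthetic_cohort_table(10_000 + rep, n_subjects=30,
                                           n_fhpos=20)
            res = run_association_battery(table)
            whole = res[res["family"] == "whole_sample"]
            hits += bool(whole["significant"].any())
        assert hits / n_rep <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / n_rep)

    def test_th_lf_followup_only_for_significant_th(self):
        # plant a strong TH-biomarker association in one group/band
        table = synthetic_cohort_table(3)
        rng = np.random.default_rng(9)
        mask = table["group"] == "FH+"
        th = table.loc[mask, metric_column("alpha", "th")]
        table.loc[mask, "biomarker"] = (
            1000 * (th - th.mean()) + 380 + rng.normal(0, 1, mask.sum()))
        res = run_association_battery(table)
        sig_th = res[(res["family"] == "subgroup") & (res["metric"] == "th")
                     & res["significant"]]
        follow = res[res["family"] == "th_lf"]
        assert len(follow) == len(sig_th)
        assert len(follow) >= 1
        got = set(zip(follow["band"], follow["group"]))
        assert got == set(zip(sig_th["band"], sig_th["group"]))
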