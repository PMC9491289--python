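"""Permutation tests, trend test, FDR, effect sizes, partial correlation, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

import richclubkit as rk
from richclubkit.datasets import clinical_summary, summary_triples


class TestPermutationTest:
    def test_exact_enumeration_small_groups(self):
        p, obs = rk.permutation_test([1, 2], [10, 11])
        assert obs == -9.0
        assert p == pytest.approx(2 / 6)

    def test_identical_constant_groups(self):
        p, _ = rk.permutation_test([3, 3, 3], [3, 3, 3])
        assert p == 1.0

    def test_sampled_matches_exact(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 6)
        p_exact, _ = rk.permutation_test(x, y, n_perm=10 ** 6)  # C(12,6)=924 -> exact
        ps = [rk.permutation_test(x, y, n_perm=800, seed=s)[0] for s in range(20)]
        se = math.sqrt(p_exact * (1 - p_exact) / 800)
        assert abs(np.mean(ps) - p_exact) < 3 * se

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rk.permutation_test([], [1, 2])

    def test_detects_large_shift(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(3, 1, 20)
        p, _ = rk.permutation_test(x, y, n_perm=2000, seed=0)
        assert p < 0.01


class TestJonckheereTerpstra:
    def test_maximal_separation(self):
        res = rk.jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == 12.0  # its maximum for sizes 2,2,2
        assert res.p == pytest.approx(1 / 90)
        assert res.method == "exact"

    def test_all_tied_half_maximum(self):
        res = rk.jonckheere_terpstra([[5, 5], [5, 5], [5, 5]])
        assert res.statistic == 6.0  # half of 12
        assert res.p == 0.5

    def test_reversal_antisymmetry(self, rng):
        gs = [rng.normal(i, 1, 7) for i in range(3)]
        fwd = rk.jonckheere_terpstra(gs)
        rev = rk.jonckheere_terpstra(gs[::-1])
        max_jt = sum(len(a) * len(b) for i, a in enumerate(gs) for b in gs[i + 1:])
        assert fwd.statistic + rev.statistic == pytest.approx(max_jt)

    def test_normal_approximation_on_larger_groups(self, rng):
        gs = [rng.normal(i * 0.8, 1, 15) for i in range(3)]
        res = rk.jonckheere_terpstra(gs)
        assert res.method == "normal"
        assert res.p < 0.05

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            rk.jonckheere_terpstra([[1, 2], [3, 4]])


class TestFdr:
    def test_step_up_by_hand(self):
        qs, reject = rk.bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert reject.sum() == 3 and not reject[3]

    def test_all_ones_no_rejections(self):
        _, reject = rk.bh_fdr([1.0, 1.0, 1.0])
        assert reject.sum() == 0

    def test_single_p(self):
        _, reject = rk.bh_fdr([0.04], q=0.05)
        assert reject[0]

    def test_monotonicity_audit(self, rng):
        for _ in range(30):
            p = rng.uniform(0.001, 1, 8)
            _, rej1 = rk.bh_fdr(p)
            i = rng.integers(8)
            p2 = p.copy()
            p2[i] = min(1.0, p2[i] * 2)
            _, rej2 = rk.bh_fdr(p2)
            assert rej2.sum() <= rej1.sum()


class TestHedgesG:
    def test_closed_form(self):
        # mean diff 1, pooled sd 1, n = 28 + 28 -> 1 * (1 - 3/215)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 28)
        x = (x - x.mean()) / x.std(ddof=1)
        y = x + 1.0
        assert rk.hedges_g(y, x) == pytest.approx(1 - 3 / 215, abs=1e-12)

    def test_identical_groups_zero(self):
        assert rk.hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_sign_flip(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert rk.hedges_g(x, y) == pytest.approx(-rk.hedges_g(y, x))

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(0, 1, 15), rng.normal(0.7, 1.3, 12)
        expected = pingouin.compute_effsize(x, y, eftype="hedges")
        assert rk.hedges_g(x, y) == pytest.approx(expected, rel=1e-6)


class TestSpearmanPartial:
    def test_monotone_transform_exact_one(self, rng):
        x = rng.normal(0, 1, 30)
        res = rk.spearman_partial(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_shared_covariate_washes_out(self, rng):
        z = rng.normal(0, 1, 200)
        res = rk.spearman_partial(2 * z + 1, -3 * z + 2, covariates=z)
        assert abs(res.rho) < 0.2

    def test_independent_covariate_keeps_signal(self, rng):
        x = rng.normal(0, 1, 50)
        z = rng.normal(0, 1, 50)
        res = rk.spearman_partial(x, x + 0.01 * rng.normal(size=50), covariates=z)
        assert res.rho > 0.95 and res.p < 1e-6

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 40
        df = pd.DataFrame({"x": rng.normal(0, 1, n), "y": rng.normal(0, 1, n),
                           "a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        df["y"] += 0.5 * df["x"] + 0.3 * df["a"]
        expected = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"],
                                         method="spearman")
        res = rk.spearman_partial(df["x"], df["y"], covariates=df[["a", "b"]])
        assert res.rho == pytest.approx(float(expected["r"].iloc[0]), abs=1e-9)

    def test_rank_deficient_covariates_rejected(self, rng):
        x = rng.normal(0, 1, 20)
        z = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="rank-deficient"):
            rk.spearman_partial(x, x, covariates=np.column_stack([z, z]))


class TestAnova:
    def test_summary_matches_raw_mode(self, rng):
        groups = [rng.normal(i, 1.5, 12) for i in range(3)]
        f_raw, df_raw, p_raw = rk.oneway_anova(groups=groups)
        summaries = [(len(g), g.mean(), g.std(ddof=1)) for g in groups]
        f_sum, df_sum, p_sum = rk.oneway_anova(summaries=summaries)
        assert f_sum == pytest.approx(f_raw, rel=1e-12)
        assert df_sum == df_raw and p_sum == pytest.approx(p_raw)

    def test_matches_scipy(self, rng):
        from scipy.stats import f_oneway
        groups = [rng.normal(i * 0.5, 1, 10) for i in range(4)]
        f_ours, _, p_ours = rk.oneway_anova(groups=groups)
        res = f_oneway(*groups)
        assert f_ours == pytest.approx(res.statistic)
        assert p_ours == pytest.approx(res.pvalue)

    def test_identical_groups_f_zero(self):
        f, _, p = rk.oneway_anova(groups=[[1, 2, 3], [1, 2, 3]])
        assert f == 0.0 and p == 1.0

    def test_clinical_summary_age_row(self):
        row = clinical_summary().loc["age"]
        f, _, _ = rk.oneway_anova(summaries=summary_triples(row))
        assert f == pytest.approx(row["reported_F"], abs=0.15)


class TestCompareCohort:
    def _measures(self, rng, effect=0.0):
        idx = [f"s{i}" for i in range(18)]
        groups = pd.Series(["A"] * 6 + ["B"] * 6 + ["C"] * 6, index=idx)
        vals = rng.normal(0, 1, 18)
        vals[6:12] += effect
        vals[12:] += 2 * effect
        return pd.DataFrame({"m": vals}, index=idx), groups

    def test_single_measure_two_groups(self, rng):
        meas, groups = self._measures(rng)
        two = meas[groups != "C"]
        table, trends = rk.compare_cohort(two, groups[groups != "C"], ("A", "B"),
                                          n_perm=200, seed=1)
        assert len(table) == 1
        assert trends == {}

    def test_per_k_family_jointly_corrected(self, rng):
        idx = [f"s{i}" for i in range(12)]
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=idx)
        meas = pd.DataFrame({f"phi@k{k}": rng.normal(0, 1, 12) for k in range(5)},
                            index=idx)
        table, _ = rk.compare_cohort(meas, groups, ("A", "B"), n_perm=200, seed=2)
        assert len(table) == 5
        assert set(table["k"]) == set(range(5))
        assert (table["q"] >= table["p_perm"] - 1e-12).all()

    def test_trend_reported_for_three_groups(self, rng):
        meas, groups = self._measures(rng, effect=1.5)
        table, trends = rk.compare_cohort(meas, groups, ("A", "B", "C"),
                                          n_perm=500, seed=3)
        assert set(table[["group_a", "group_b"]].itertuples(index=False, name=None)) \
            == {("A", "B"), ("A", "C"), ("B", "C")}
        assert trends["m"].p < 0.05

    def test_deterministic_given_seed(self, rng):
        meas, groups = self._measures(rng, effect=0.5)
        t1, _ = rk.compare_cohort(meas, groups, ("A", "B", "C"), n_perm=300, seed=9)
        t2, _ = rk.compare_cohort(meas, groups, ("A", "B", "C"), n_perm=300, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
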