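"""Classical statistics: ANOVA, letters, t-tests, PCA, SMA, variance
partitioning and the multi-level correlation table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from resorb.simulate import simulate_tree, simulate_bm_traits
from resorb.stats import (
    correlation_table,
    letter_groups,
    one_sample_t,
    one_way_anova,
    pca_elements,
    sma_fit,
    two_sample_t,
    variance_partition,
)


class TestAnova:
    def test_hand_decomposition(self):
        res = one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_means_give_zero_f(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        res = one_way_anova(np.r_[x, y], ["a"] * 12 + ["b"] * 9)
        t = sps.ttest_ind(x, y, equal_var=True)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_ss_conservation(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=30)
        labs = rng.choice(list("abc"), 30)
        res = one_way_anova(vals, labs)
        total = ((vals - vals.mean()) ** 2).sum()
        assert res.ss_between + res.ss_within == pytest.approx(total, abs=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 2)]
        res = one_way_anova(np.concatenate(groups), ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


class TestLetters:
    def test_separated_groups(self):
        vals = [10, 11, 10.5, 0, 1, 0.5]
        labs = ["hi"] * 3 + ["lo"] * 3
        letters = letter_groups(vals, labs)
        assert letters == {"hi": "a", "lo": "b"}

    def test_identical_groups_share_letter(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labs = ["x"] * 3 + ["y"] * 3
        letters = letter_groups(vals, labs)
        assert letters["x"] == letters["y"] == "a"

    def test_letters_follow_descending_means(self):
        rng = np.random.default_rng(4)
        vals = np.r_[rng.normal(0, 1, 10), rng.normal(20, 1, 10), rng.normal(40, 1, 10)]
        labs = ["lo"] * 10 + ["mid"] * 10 + ["hi"] * 10
        letters = letter_groups(vals, labs)
        assert letters == {"hi": "a", "mid": "b", "lo": "c"}


class TestTTests:
    def test_symmetric_sample_vs_zero(self):
        t, p = one_sample_t([-1.0, 0.0, 1.0], 0.0)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_degenerate_constant_sample(self):
        with pytest.raises(ValueError):
            one_sample_t([5.0, 5.0, 5.0], 0.0)
        t, p = one_sample_t([5.0, 5.0, 5.0], 5.0)
        assert p == 1.0

    def test_welch_against_summary_matches_vector_form(self):
        rng = np.random.default_rng(5)
        x, ref = rng.normal(1, 1, 20), rng.normal(0, 2, 50)
        t1, p1 = two_sample_t(x, ref)
        t2, p2 = two_sample_t(x, (ref.mean(), ref.std(ddof=1), len(ref)))
        assert t1 == pytest.approx(t2, rel=1e-10) and p1 == pytest.approx(p2, rel=1e-10)

    def test_power_against_generated_re(self):
        rng = np.random.default_rng(6)
        re = rng.normal(60, 10, 36)  # strong resorption across 36 species
        _, p = one_sample_t(re, 0.0)
        assert p < 1e-3


class TestPca:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        loadings, varexp = pca_elements(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert varexp[0] == pytest.approx(100.0)

    def test_half_correlated_closed_form(self):
        # correlation r gives eigenvalues 1+r, 1-r: PC1 explains 75% at r=0.5
        rng = np.random.default_rng(8)
        z1, z2 = rng.normal(size=(2, 200_000))
        x = z1
        y = 0.5 * z1 + np.sqrt(1 - 0.25) * z2
        _, varexp = pca_elements(pd.DataFrame({"x": x, "y": y}))
        assert varexp[0] == pytest.approx(75.0, abs=1.0)

    def test_orthonormal_loadings_and_variance_conservation(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("NPKXCM"))
        loadings, varexp = pca_elements(X)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(6), atol=1e-9)
        assert varexp.sum() == pytest.approx(100.0, abs=1e-9)

    def test_constant_column_named(self):
        X = pd.DataFrame({"N": [1.0, 2.0, 3.0], "Na": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="Na"):
            pca_elements(X)


class TestSma:
    def test_exact_line(self):
        fit = sma_fit([1, 2, 3, 4], [2, 4, 6, 8])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_worked_example(self):
        fit = sma_fit([1, 2, 3, 4], [1, 3, 2, 5])
        assert fit.slope == pytest.approx(1.3229, abs=1e-4)
        assert fit.intercept == pytest.approx(-0.5572, abs=1e-4)
        assert fit.r == pytest.approx(0.8315, abs=1e-4)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            sma_fit([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_reciprocity_and_ols_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = 0.6 * x + rng.normal(size=15)
        fxy, fyx = sma_fit(x, y), sma_fit(y, x)
        assert fxy.slope * fyx.slope == pytest.approx(1.0, abs=1e-8)
        ols = np.polyfit(x, y, 1)[0]
        assert fxy.slope == pytest.approx(ols / abs(fxy.r), abs=1e-8)


class TestVariancePartition:
    def test_single_determining_factor(self):
        vp = variance_partition([1, 1, 2, 2], pd.DataFrame({"f": ["a", "a", "b", "b"]}))
        assert vp.proportions["f"] == pytest.approx(1.0)
        assert vp.residual == pytest.approx(0.0, abs=1e-12)

    def test_sequential_order_hand_example(self):
        factors = pd.DataFrame(
            {"site": ["s1", "s1", "s2", "s2"], "group": ["g1", "g2", "g1", "g2"]}
        )
        vp = variance_partition([1, 1, 2, 2], factors)
        assert vp.proportions["site"] == pytest.approx(1.0)
        assert vp.proportions["group"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_on_clean_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "site": rng.choice(["s1", "s2", "s3"], 60),
                "group": rng.choice(["g1", "g2", "g3", "g4"], 60),
                "y": rng.normal(size=60),
            }
        )
        df["y"] += df["group"].map({"g1": 0, "g2": 1, "g3": 2, "g4": 0.5})
        vp = variance_partition(df["y"], df[["site", "group"]])
        anova = sm.stats.anova_lm(smf.ols("y ~ C(site) + C(group)", df).fit(), typ=1)
        total = anova["sum_sq"].sum()
        assert vp.proportions["site"] == pytest.approx(anova.loc["C(site)", "sum_sq"] / total, abs=1e-8)
        assert vp.proportions["group"] == pytest.approx(anova.loc["C(group)", "sum_sq"] / total, abs=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 100))
    def test_sums_to_one_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=24)
        factors = pd.DataFrame(
            {"a": rng.choice(["x", "y"], 24), "b": rng.choice(["u", "v", "w"], 24)}
        )
        vp = variance_partition(y, factors)
        assert sum(vp.proportions.values()) + vp.residual == pytest.approx(1.0, abs=1e-9)
        vp2 = variance_partition(y * scale, factors)
        for k in vp.proportions:
            assert vp2.proportions[k] == pytest.approx(vp.proportions[k], abs=1e-8)

    def test_fully_aliased_factor_rejected(self):
        factors = pd.DataFrame(
            {"a": ["x", "x", "y", "y"], "b": ["u", "u", "v", "v"]}
        )
        with pytest.raises(ValueError, match="aliased"):
            variance_partition([1.0, 2.0, 3.0, 4.0], factors)


class TestCorrelationTable:
    def test_perfect_negative_at_every_level(self):
        rng = np.random.default_rng(11)
        tree = simulate_tree(12, seed=12)
        x = simulate_bm_traits(tree, seed=13)["trait1"]
        species = pd.DataFrame({"u": x, "v": -x})
        ind = pd.DataFrame({"u": rng.normal(size=40)})
        ind["v"] = -ind["u"]
        table = correlation_table([("u", "v")], individual=ind, species=species, tree=tree)
        row = table.iloc[0]
        assert row["individual_r"] == pytest.approx(-1.0)
        assert row["species_r"] == pytest.approx(-1.0)
        assert row["species_PIC_r"] == pytest.approx(-1.0)

    def test_level_sample_sizes(self):
        tree = simulate_tree(36, seed=14)
        species = pd.DataFrame(
            {
                "u": simulate_bm_traits(tree, seed=15)["trait1"],
                "v": simulate_bm_traits(tree, seed=16)["trait1"],
            }
        )
        table = correlation_table([("u", "v")], species=species, tree=tree)
        row = table.iloc[0]
        assert row["species_n"] == 36 and row["species_PIC_n"] == 35
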