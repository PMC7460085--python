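import itertools

import numpy as np
import pandas as pd
import pytest

from fametraj.fame import DlPolicy
from fametraj.univariate import (
    GroupedValues,
    auto_anova,
    bartlett,
    levene,
    significance_stars,
    three_way_anova,
    univariate_screen,
)

from . import oracles


def gv(*arrays):
    return GroupedValues([(f"g{i}", np.asarray(a, float)) for i, a in enumerate(arrays)])


class TestBartlett:
    def test_shifted_copies_have_equal_variance(self):
        base = [1.0, 2.0, 4.0, 7.0]
        stat, p = bartlett(gv(base, [x + 10 for x in base], [x - 5 for x in base]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_heteroscedastic_groups_detected(self):
        stat, p = bartlett(gv([1, 2, 3], [10, 20, 30], [100, 200, 300]))
        o_stat, o_p = oracles.bartlett_stat(
            [np.array([1, 2, 3.0]), np.array([10, 20, 30.0]), np.array([100, 200, 300.0])]
        )
        assert p < 0.01
        assert stat == pytest.approx(o_stat, rel=1e-10)
        assert p == pytest.approx(o_p, rel=1e-10)

    def test_duplicated_group_statistic_zero(self):
        stat, _ = bartlett(gv([1, 5, 9], [1, 5, 9], [1, 5, 9]))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            bartlett(gv([1, 1, 1], [1, 2, 3]))


class TestStars:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, "n.s."), (0.05, "n.s."), (0.049, "*"), (0.02, "*"), (0.01, "*"), (0.009, "**"), (0.001, "**"), (0.0005, "***"), (0.0, "***"), (1.0, "n.s.")],
    )
    def test_threshold_mapping(self, p, stars):
        assert significance_stars(p) == stars

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestAutoAnova:
    def test_classical_route_hand_computed(self):
        """Three shifted groups: SSB=6, SSW=6 → F = 3.0 on (2, 6) df."""
        res = auto_anova(gv([1, 2, 3], [2, 3, 4], [3, 4, 5]))
        assert res.method == "classical"
        assert res.F == pytest.approx(3.0, rel=1e-12)
        assert (res.df_num, res.df_den) == (2, 6)

    def test_identical_groups_give_zero_F(self):
        res = auto_anova(gv([1, 2, 3], [1, 2, 3], [1, 2, 3]))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_heteroscedastic_routes_to_welch(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(0, 10.0, 10)
        c = rng.normal(0, 5.0, 10)
        res = auto_anova(gv(a, b, c))
        assert res.method == "welch"
        F, df1, df2, p = oracles.oneway_welch([a, b, c])
        assert res.F == pytest.approx(F, rel=1e-8)
        assert res.df_den == pytest.approx(df2, rel=1e-8)
        assert res.p == pytest.approx(p, rel=1e-8)

    def test_welch_agrees_with_classical_for_two_equal_groups(self, rng):
        """Two groups of identical size and spread: Welch F equals classical F.

        (With three or more groups Welch's correction factor shrinks F even
        under exactly equal variances, so exact agreement is pairwise only.)
        """
        base = rng.normal(0, 1, 8)
        groups = [base, base + 1.0]  # identical variances
        cls = auto_anova(gv(*groups))
        F_w, _, df2_w, _ = oracles.oneway_welch(groups)
        assert F_w == pytest.approx(cls.F, abs=1e-6)
        assert df2_w <= cls.df_den
        # the df bound holds for k > 2 as well
        three = [base, base + 1.0, base - 0.5]
        _, _, df2_3, _ = oracles.oneway_welch(three)
        assert df2_3 <= auto_anova(gv(*three)).df_den

    def test_oracle_equivalence_random_datasets(self, rng):
        """Classical, Welch and Levene match textbook formulas on random data."""
        for _ in range(100):
            k = rng.integers(2, 6)
            groups = [rng.normal(rng.normal(0, 2), rng.uniform(0.5, 3), rng.integers(3, 12)) for _ in range(k)]
            g = gv(*groups)
            res_c = auto_anova(g, alpha_hetero=1e-12)  # force classical
            F, df1, df2, p = oracles.oneway_classical(groups)
            assert res_c.method == "classical"
            assert res_c.F == pytest.approx(F, rel=1e-8)
            assert res_c.p == pytest.approx(p, rel=1e-8)
            res_w = auto_anova(g, alpha_hetero=1 - 1e-12)  # force welch
            F, df1, df2, p = oracles.oneway_welch(groups)
            assert res_w.method == "welch"
            assert res_w.F == pytest.approx(F, rel=1e-8)
            assert res_w.p == pytest.approx(p, rel=1e-8)
            _, _, stat, p_l = levene(g)
            F_l, p_lo = oracles.levene_median(groups)
            assert stat == pytest.approx(F_l, rel=1e-8)
            assert p_l == pytest.approx(p_lo, rel=1e-8)

    def test_sum_of_squares_partition(self, rng):
        """SSB + SSW = SST for the classical decomposition."""
        groups = [rng.normal(i, 1 + i, 6) for i in range(4)]
        all_vals = np.concatenate(groups)
        sst = ((all_vals - all_vals.mean()) ** 2).sum()
        ssb = sum(len(g) * (g.mean() - all_vals.mean()) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        assert ssb + ssw == pytest.approx(sst, rel=1e-9)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            GroupedValues([("a", np.array([1.0, 2.0]))])
        with pytest.raises(ValueError):
            GroupedValues([("a", np.array([1.0, 2.0])), ("b", np.array([1.0]))])


def balanced_design(n_rep=3):
    rows = list(
        itertools.product(["LD", "SL"], [10, 18, 25], [23.5, 50, 70], range(1, n_rep + 1))
    )
    return pd.DataFrame(rows, columns=["host", "temperature", "salinity", "replicate"])


class TestThreeWayAnova:
    def test_design_degrees_of_freedom(self, rng):
        df = balanced_design()
        df["value"] = rng.normal(size=len(df))
        table = three_way_anova(df)
        expected_df = {
            "host": 1, "temp": 2, "sal": 2,
            "host:temp": 2, "host:sal": 2, "temp:sal": 4, "host:temp:sal": 4,
            "residual": 36,
        }
        assert table["df"].to_dict() == expected_df

    def test_constant_response(self):
        df = balanced_design()
        df["value"] = 5.0
        table = three_way_anova(df)
        assert np.allclose(table["sum_sq"], 0, atol=1e-20)
        terms = table.drop(index="residual")
        assert np.allclose(terms["F"], 0)

    def test_pure_host_effect(self):
        df = balanced_design()
        df["value"] = np.where(df["host"] == "LD", 1.0, 0.0)
        table = three_way_anova(df)
        assert table.loc["host", "sum_sq"] > 0
        others = table.drop(index=["host", "residual"])
        assert np.allclose(others["sum_sq"], 0, atol=1e-18)
        assert table.loc["residual", "sum_sq"] == pytest.approx(0, abs=1e-18)

    def test_matches_cell_mean_decomposition(self, rng):
        """Every SS term equals the brute-force balanced decomposition oracle."""
        df = balanced_design()
        df["value"] = rng.normal(size=len(df)) + np.where(df["host"] == "LD", 0.5, 0) + df["temperature"] * 0.01
        table = three_way_anova(df)
        ss = oracles.three_way_ss(
            df["value"].to_numpy(),
            df["host"].to_numpy(),
            df["temperature"].to_numpy(),
            df["salinity"].to_numpy(),
        )
        mapping = {
            "host": "a", "temp": "b", "sal": "c",
            "host:temp": "ab", "host:sal": "ac", "temp:sal": "bc",
            "host:temp:sal": "abc", "residual": "residual",
        }
        for term, key in mapping.items():
            assert table.loc[term, "sum_sq"] == pytest.approx(ss[key], rel=1e-9), term
        assert table["sum_sq"].sum() == pytest.approx(
            ((df["value"] - df["value"].mean()) ** 2).sum(), rel=1e-9
        )

    def test_factor_order_invariance(self, rng):
        df = balanced_design()
        df["value"] = rng.normal(size=len(df))
        t1 = three_way_anova(df)
        shuffled = df.sample(frac=1, random_state=0).reset_index(drop=True)
        t2 = three_way_anova(shuffled)
        for term in t1.index:
            assert t1.loc[term, "sum_sq"] == pytest.approx(t2.loc[term, "sum_sq"], rel=1e-9)

    def test_unbalanced_design_rejected(self, rng):
        df = balanced_design().iloc[:-1]
        df = df.assign(value=rng.normal(size=len(df)))
        with pytest.raises(ValueError, match="unbalanced"):
            three_way_anova(df)


class TestLevene:
    def test_degrees_of_freedom_for_18_triplicate_groups(self, rng):
        """18 groups of 3 → df1 = 17 and df2 = 36."""
        groups = [(f"g{i}", rng.normal(0, 1, 3)) for i in range(18)]
        df1, df2, stat, p = levene(GroupedValues(groups))
        assert (df1, df2) == (17, 36)

    def test_equal_variances_near_zero_statistic(self):
        base = np.array([1.0, 2.0, 4.0, 8.0])
        _, _, stat, p = levene(gv(base, base + 3, base - 2))
        assert stat == pytest.approx(0.0, abs=1e-12)


class TestScreen:
    def test_screen_on_simulated_profiles(self, sim_profiles):
        """The per-fatty-acid screen runs per host × salinity and skips below-dl strata."""
        out = univariate_screen(sim_profiles, DlPolicy())
        assert set(out["method"]) <= {"classical", "welch"}
        assert (out["df_num"] == 2).all()  # three temperatures per comparison
        # 12:0 is below detection in every SL cell: no SL rows for it
        assert out[(out.fatty_acid == "12:0") & (out.host == "SL")].empty
        # 18:2n-6 is quantified everywhere: testable in all 6 host×salinity strata;
        # 18:1n-9 loses the stratum containing the unprinted LD/18°C/50PSU cell
        assert len(out[out.fatty_acid == "18:2n-6"]) == 6
        assert len(out[out.fatty_acid == "18:1n-9"]) == 5
        assert set(out.columns) >= {"fatty_acid", "host", "salinity_psu", "F", "p", "stars", "bartlett_p"}
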