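"""ANOVA / Tukey / Levene / regression against brute-force computation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from thermoperf.stats import (
    StatsError,
    effort_epoc_regression,
    levene,
    one_way_anova,
    sensitivity_anova,
    two_way_anova,
)


def long_frame(groups: dict[str, list[float]], group_col="temperature"):
    rows = [
        {group_col: g, "value": v} for g, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


class TestOneWayAnova:
    def test_identical_groups_f_zero_p_one(self):
        table = long_frame({"a": [5.0] * 4, "b": [5.0] * 4})
        res = one_way_anova(table)
        assert res.p_for("temperature") == 1.0
        assert res.terms["F"].iloc[0] == 0.0

    def test_matches_brute_force_sums_of_squares(self):
        groups = {
            "g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
            "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
            "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0],
        }
        res = one_way_anova(long_frame(groups))
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(
            len(v) * (np.mean(v) - grand) ** 2 for v in groups.values()
        )
        ss_within = sum(
            ((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values()
        )
        f = (ss_between / 2) / (ss_within / (len(all_vals) - 3))
        p = scipy.stats.f.sf(f, 2, len(all_vals) - 3)
        assert res.terms["F"].iloc[0] == pytest.approx(f, rel=1e-9)
        assert res.p_for("temperature") == pytest.approx(p, rel=1e-9)

    def test_tukey_adjusted_p_not_below_pairwise_p(self):
        rng = np.random.default_rng(2)
        groups = {g: list(rng.normal(i * 0.5, 1.0, 10)) for i, g in
                  enumerate("abcd")}
        res = one_way_anova(long_frame(groups))
        for row in res.tukey.itertuples(index=False):
            raw = scipy.stats.ttest_ind(
                groups[row.group_1], groups[row.group_2]
            ).pvalue
            assert float(row.p_adjusted) >= raw - 1e-9

    def test_degenerate_input_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova(long_frame({"a": [1.0]}))


class TestTwoWayAnova:
    def make_table(self, effect_b=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for t in (14, 8, 2):
            for b in ("acute", "acclimated"):
                mu = effect_b * (b == "acclimated")
                for v in rng.normal(mu, 1.0, 6):
                    rows.append(
                        {"temperature": t, "treatment": b, "value": v}
                    )
        return pd.DataFrame(rows)

    def test_identical_observations_give_zero_f(self):
        table = self.make_table()
        table["value"] = 3.0
        res = two_way_anova(table)
        assert (res.terms["F"] == 0.0).all()
        assert (res.terms["p"] == 1.0).all()

    def test_sums_of_squares_partition_balanced(self):
        table = self.make_table(effect_b=1.0, seed=3)
        res = two_way_anova(table)
        y = table["value"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        cell_means = table.groupby(["temperature", "treatment"])[
            "value"
        ].transform("mean")
        ss_error = ((y - cell_means) ** 2).sum()
        assert res.terms["ss"].sum() + ss_error == pytest.approx(
            ss_total, rel=1e-9
        )

    def test_empty_cell_named_in_error(self):
        table = self.make_table()
        table = table[
            ~((table["temperature"] == 2) & (table["treatment"] == "acute"))
        ]
        with pytest.raises(StatsError, match="2"):
            two_way_anova(table)

    def test_strong_treatment_effect_detected(self):
        res = two_way_anova(self.make_table(effect_b=3.0, seed=1))
        assert res.p_for("treatment") < 1e-6


class TestSensitivityAnova:
    def test_identical_levels_give_zero_f(self):
        table = pd.DataFrame(
            {
                "level": ["acute 14-8"] * 3 + ["acute 8-2"] * 3,
                "value": [2.0, 3.0, 4.0] * 2,
                "metric": ["m1", "m2", "m3"] * 2,
            }
        )
        res = sensitivity_anova(table)
        assert res.terms["F"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_metric_order_invariance(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {
                "level": np.repeat(["a", "b", "c"], 5),
                "value": rng.normal(0, 1, 15),
                "metric": list("mnopq") * 3,
            }
        )
        shuffled = table.sample(frac=1.0, random_state=9)
        assert sensitivity_anova(table).p_for("level") == pytest.approx(
            sensitivity_anova(shuffled).p_for("level"), rel=1e-9
        )

    def test_single_metric_per_level_rejected(self):
        table = pd.DataFrame(
            {"level": ["a", "b"], "value": [1.0, 2.0], "metric": ["m", "m"]}
        )
        with pytest.raises(StatsError):
            sensitivity_anova(table)


class TestLevene:
    def test_shifted_identical_groups_give_w_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w, p = levene([base, base + 10.0, base - 3.0])
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_matches_anova_on_absolute_deviations(self):
        g1 = np.array([1.0, 4.0, 2.0])
        g2 = np.array([10.0, 2.0, 6.0])
        w, p = levene([g1, g2])
        d1, d2 = np.abs(g1 - g1.mean()), np.abs(g2 - g2.mean())
        f, p_ref = scipy.stats.f_oneway(d1, d2)
        assert w == pytest.approx(f, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(StatsError):
            levene([np.array([1.0])])


class TestEffortEpocRegression:
    def make_table(self, slope_acc=2.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for treatment, slope in (("acute", 2.0), ("acclimated", slope_acc)):
            for x in (100.0, 200.0, 300.0, 400.0, 500.0):
                rows.append(
                    {
                        "treatment": treatment,
                        "effort": x,
                        "epoc": slope * x + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_line_recovered(self):
        res = effort_epoc_regression(self.make_table())
        for row in res.per_group.itertuples(index=False):
            assert row.slope == pytest.approx(2.0, rel=1e-9)
            assert row.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_outlier_slope_matches_normal_equations(self):
        table = self.make_table(noise=0.0)
        table.loc[2, "epoc"] += 150.0  # one outlier among collinear points
        res = effort_epoc_regression(table)
        grp = table[table["treatment"] == "acute"]
        x, y = grp["effort"].to_numpy(), grp["epoc"].to_numpy()
        beta = ((x - x.mean()) * (y - y.mean())).sum() / (
            (x - x.mean()) ** 2
        ).sum()
        got = res.per_group.set_index("treatment").loc["acute", "slope"]
        assert got == pytest.approx(beta, rel=1e-9)

    def test_different_slopes_detected(self):
        res = effort_epoc_regression(
            self.make_table(slope_acc=4.0, noise=5.0, seed=1)
        )
        assert res.interaction_p < 0.01
        assert res.slopes_differ

    def test_too_few_points_rejected(self):
        table = self.make_table().iloc[:7]
        with pytest.raises(StatsError):
            effort_epoc_regression(table)
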