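"""Delta notation, variance-based isotopic niche metrics, ANOVA and t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import scatniche as sn


def iso_frame(groups: dict[tuple[str, int], list[float]], isotope="d15N") -> pd.DataFrame:
    rows = []
    for (river, year), values in groups.items():
        for i, v in enumerate(values):
            rows.append((f"{river}{year}-{i}", river, year, v, v))
    return pd.DataFrame(rows, columns=["scat_id", "river", "year", "d15N", "d13C"])


def levene_by_hand(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F on absolute deviations from group means (oracle)."""
    z = [np.abs(g - g.mean()) for g in groups]
    allz = np.concatenate(z)
    k = len(z)
    n = allz.size
    ss_between = sum(g.size * (g.mean() - allz.mean()) ** 2 for g in z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in z)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def welch_df_by_hand(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))


class TestDeltaValue:
    def test_sample_equal_to_standard_is_zero(self):
        assert sn.delta_value(0.0036765, 0.0036765) == 0.0

    def test_hand_arithmetic(self):
        assert sn.delta_value(1.0034 * 0.011, 0.011) == pytest.approx(3.4, abs=1e-9)

    def test_depleted_sample_is_negative(self):
        assert sn.delta_value(0.9 * 0.011, 0.011) < 0

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValueError):
            sn.delta_value(0.01, 0.0)


class TestVarianceNiche:
    def test_sample_variance_of_1_2_3_is_one(self):
        df = iso_frame({("A", 2010): [1, 2, 3], ("B", 2010): [4, 5, 7]})
        out = sn.variance_niche(df, "d15N")
        row = out.per_group[(out.per_group.river == "A")].iloc[0]
        assert row.variance == pytest.approx(1.0)

    def test_shifted_groups_have_identical_spread(self):
        df = iso_frame({("A", 2010): [1, 2, 3], ("B", 2010): [4, 5, 6]})
        out = sn.variance_niche(df, "d15N")
        assert out.omnibus.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.omnibus.pvalue == pytest.approx(1.0)

    def test_levene_matches_hand_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 2, 12)
        b = rng.normal(5, 1, 9)
        df = iso_frame({("A", 2010): list(a), ("B", 2010): list(b)})
        out = sn.variance_niche(df, "d15N", center="mean")
        assert out.omnibus.statistic == pytest.approx(
            levene_by_hand([a, b]), abs=1e-10
        )

    def test_levene_invariant_to_shifting_one_group(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 2, 10), rng.normal(0, 1, 10)
        w1 = sn.variance_niche(iso_frame({("A", 1): list(a), ("B", 1): list(b)}), "d15N")
        w2 = sn.variance_niche(iso_frame({("A", 1): list(a + 100), ("B", 1): list(b)}), "d15N")
        assert w1.omnibus.statistic == pytest.approx(w2.omnibus.statistic, rel=1e-9)

    def test_variance_scales_quadratically(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, 40)
        df1 = iso_frame({("A", 1): list(v), ("B", 1): list(v)})
        df3 = iso_frame({("A", 1): list(3 * v), ("B", 1): list(3 * v)})
        v1 = sn.variance_niche(df1, "d15N").per_group.variance.iloc[0]
        v3 = sn.variance_niche(df3, "d15N").per_group.variance.iloc[0]
        assert v3 == pytest.approx(9 * v1)

    def test_group_below_two_samples_is_error_naming_group(self):
        df = iso_frame({("A", 2010): [1.0], ("B", 2010): [4, 5, 6]})
        with pytest.raises(ValueError, match="A 2010"):
            sn.variance_niche(df, "d15N")

    def test_detects_study_variance_contrast_in_majority_of_replicates(self):
        """Power: sigma^2 4.83 (n=20) vs 1.73 (n=55) rejected at alpha=0.05
        in most seeded replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0, np.sqrt(4.83), 20)
            b = rng.normal(0, np.sqrt(1.73), 55)
            _, p = stats.levene(a, b, center="mean")
            rejections += p < 0.05
        assert rejections / n_rep > 0.5


class TestNormalityCheck:
    def test_normal_draws_pass_in_majority_of_seeds(self):
        passes = 0
        for seed in range(20):
            v = np.random.default_rng(seed).normal(10, 2, 50)
            passes += sn.normality_check(v).verdict == "normal"
        assert passes >= 15

    def test_constant_vector_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            assert sn.normality_check([5.0] * 10).verdict == "degenerate"

    def test_too_small_sample_not_assessed(self):
        with pytest.warns(UserWarning, match="not assessed"):
            assert sn.normality_check([1.0, 2.0]).verdict == "not assessed"


class TestTwoFactorAnova:
    def test_equal_cell_means_give_near_zero_f(self):
        rng = np.random.default_rng(4)
        river = ["A"] * 20 + ["B"] * 20
        year = ([2010] * 10 + [2015] * 10) * 2
        y = 10 + rng.normal(0, 1, 40)  # no structure
        res = sn.anova_two_factor(y, river, year, log_transform=False)
        assert res.f("river") < 5 and res.f("year") < 5  # no signal, F ~ O(1)
        assert res.p("river") > 0.01

    def test_balanced_2x2_matches_textbook_decomposition(self):
        # 2 replicates per cell; closed-form sequential SS for a balanced design
        data = {
            ("A", 2010): [10.0, 12.0],
            ("A", 2015): [14.0, 16.0],
            ("B", 2010): [11.0, 13.0],
            ("B", 2015): [19.0, 21.0],
        }
        y, river, year = [], [], []
        for (r, yr), vals in data.items():
            for v in vals:
                y.append(v), river.append(r), year.append(yr)
        y = np.asarray(y)
        grand = y.mean()
        mean_r = {r: np.mean([v for (rr, _), vals in data.items() for v in vals if rr == r]) for r in "AB"}
        mean_y = {t: np.mean([v for (_, tt), vals in data.items() for v in vals if tt == t]) for t in (2010, 2015)}
        ss_river = 4 * sum((m - grand) ** 2 for m in mean_r.values())
        ss_year = 4 * sum((m - grand) ** 2 for m in mean_y.values())
        cell_means = {k: np.mean(v) for k, v in data.items()}
        ss_inter = 2 * sum(
            (cell_means[(r, t)] - mean_r[r] - mean_y[t] + grand) ** 2
            for r in "AB"
            for t in (2010, 2015)
        )
        ss_resid = sum((v - cell_means[k]) ** 2 for k, vals in data.items() for v in vals)
        res = sn.anova_two_factor(y, river, year, log_transform=False)
        assert res.table.loc["river", "sum_sq"] == pytest.approx(ss_river, abs=1e-10)
        assert res.table.loc["year", "sum_sq"] == pytest.approx(ss_year, abs=1e-10)
        assert res.table.loc["interaction", "sum_sq"] == pytest.approx(ss_inter, abs=1e-10)
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(ss_resid, abs=1e-10)

    def test_log_transform_requires_positive_values(self):
        with pytest.raises(ValueError, match="positive"):
            sn.anova_two_factor(
                [-1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"], [1, 2, 1, 2], log_transform=True
            )

    def test_empty_cell_is_an_error_naming_the_cell(self):
        with pytest.raises(ValueError, match="empty design cell"):
            sn.anova_two_factor(
                [1.0, 2.0, 3.0], ["A", "A", "B"], [2010, 2015, 2010], log_transform=False
            )

    def test_zero_residual_variance_is_an_error(self):
        with pytest.raises(ValueError, match="residual"):
            sn.anova_two_factor(
                [1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"], [2010, 2015, 2010, 2015],
                log_transform=False,
            )


class TestPairwiseTBonferroni:
    def test_identical_groups_give_t_zero_p_one(self):
        v = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        g = ["A"] * 3 + ["B"] * 3
        out = sn.pairwise_t_bonferroni(v, g, [("A", "B")], equal_var_policy="pooled")
        assert out.t.iloc[0] == pytest.approx(0.0)
        assert out.p_adj.iloc[0] == pytest.approx(1.0)

    def test_welch_df_matches_satterthwaite_formula(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 3, 8)
        b = rng.normal(1, 1, 25)
        v = np.concatenate([a, b])
        g = ["A"] * 8 + ["B"] * 25
        out = sn.pairwise_t_bonferroni(v, g, [("A", "B")], equal_var_policy="welch")
        assert out.df.iloc[0] == pytest.approx(welch_df_by_hand(a, b), abs=1e-10)

    def test_single_contrast_keeps_raw_p(self):
        rng = np.random.default_rng(8)
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)])
        g = ["A"] * 10 + ["B"] * 10
        out = sn.pairwise_t_bonferroni(v, g, [("A", "B")], equal_var_policy="pooled")
        assert out.p_adj.iloc[0] == pytest.approx(out.p_raw.iloc[0])

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(9)
        v = np.concatenate([rng.normal(i * 0.3, 1, 12) for i in range(3)])
        g = ["A"] * 12 + ["B"] * 12 + ["C"] * 12
        out = sn.pairwise_t_bonferroni(
            v, g, [("A", "B"), ("A", "C"), ("B", "C")], equal_var_policy="auto"
        )
        assert (out.p_adj >= out.p_raw - 1e-15).all()
        assert (out.p_adj <= 1.0).all()

    def test_unknown_group_in_contrast_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            sn.pairwise_t_bonferroni([1.0, 2.0], ["A", "A"], [("A", "Z")])
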