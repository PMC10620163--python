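"""Statistics: Welch ANOVA, post-hocs, mixed design, power, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vrgaze.stats_engine import (
    GroupSummary,
    ancova,
    games_howell,
    hedges_g,
    holm_bonferroni,
    levene_test,
    mixed_anova,
    power_min_n,
    shapiro_wilk,
    simple_main_effects,
    summaries_from_raw,
    summarize_groups,
    welch_anova,
)


class TestSummaries:
    def test_ci_collapses_when_sd_zero(self):
        table = summarize_groups([GroupSummary("a", 10, 5.0, 0.0), GroupSummary("b", 5, 2.0, 1.0)])
        row = table.iloc[0]
        assert row["ci_low"] == row["ci_high"] == pytest.approx(5.0)

    def test_pooled_row_is_weighted_mean(self):
        table = summarize_groups(
            [GroupSummary("a", 10, 100.0, 5.0), GroupSummary("b", 30, 200.0, 5.0)]
        )
        assert table.iloc[-1]["mean"] == pytest.approx(175.0)
        assert table.iloc[-1]["n"] == 40

    def test_pooled_sd_reproduces_raw_total_sd(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 40), rng.normal(14, 5, 25)
        df = pd.DataFrame(
            {"group": ["a"] * 40 + ["b"] * 25, "v": np.concatenate([a, b])}
        )
        table = summarize_groups(summaries_from_raw(df, "v"))
        assert table.iloc[-1]["sd"] == pytest.approx(
            np.concatenate([a, b]).std(ddof=1), rel=1e-12
        )

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups([GroupSummary("a", 1, 0.0, 0.0)])


class TestWelchAnova:
    def test_two_groups_equals_squared_welch_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 3, 40)
        res = welch_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=False)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_identical_means_give_zero_F(self):
        res = welch_anova(
            [GroupSummary("a", 10, 5.0, 1.0), GroupSummary("b", 12, 5.0, 2.0)]
        )
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, s, 25) for m, s in [(0, 1), (1, 2), (2, 0.5)]]
        ms = welch_anova(groups)
        secs = welch_anova([g / 1000.0 for g in groups])
        assert secs.F == pytest.approx(ms.F, rel=1e-9)
        assert secs.df2 == pytest.approx(ms.df2, rel=1e-9)
        assert secs.omega_sq == pytest.approx(ms.omega_sq, rel=1e-9)

    def test_raw_equals_summary_round_trip(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i, 1 + i, 20) for i in range(4)}
        raw = welch_anova(groups)
        summ = welch_anova(
            [
                GroupSummary(k, len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
                for k, v in groups.items()
            ]
        )
        assert raw == summ

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([GroupSummary("a", 10, 1.0, 0.0), GroupSummary("b", 10, 2.0, 1.0)])

    def test_agrees_with_pingouin_on_raw_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "g": np.repeat(list("abcd"), 25),
                "v": np.concatenate(
                    [rng.normal(m, s, 25) for m, s in [(0, 1), (0.4, 2), (1, 1), (0, 3)]]
                ),
            }
        )
        mine = welch_anova({g: sub["v"].to_numpy() for g, sub in df.groupby("g")})
        ref = pg.welch_anova(data=df, dv="v", between="g")
        assert mine.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert mine.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)


class TestGamesHowell:
    def test_identical_groups(self):
        res = games_howell(
            [GroupSummary("a", 20, 5.0, 1.0), GroupSummary("b", 20, 5.0, 1.0)]
        )
        assert res[0].mean_diff == 0.0
        assert res[0].p_adj == pytest.approx(1.0, abs=1e-9)

    def test_two_group_p_equals_welch_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 25), rng.normal(0.8, 2.5, 35)
        res = games_howell([a, b])[0]
        t = stats.ttest_ind(a, b, equal_var=False)
        assert res.p_adj == pytest.approx(t.pvalue, rel=1e-6)

    def test_pairwise_p_matches_permutation_reference(self):
        """GH p approximates the permutation null of the studentized range."""
        rng = np.random.default_rng(6)
        k, n = 3, 30
        data = [rng.normal(0, 1, n) for _ in range(k)]
        data[2] = data[2] + 0.65
        res = games_howell(data)

        def pair_q(groups):
            qs = {}
            for i in range(k):
                for j in range(i + 1, k):
                    se = np.sqrt(
                        (groups[i].var(ddof=1) / n + groups[j].var(ddof=1) / n) / 2
                    )
                    qs[(i, j)] = abs(groups[i].mean() - groups[j].mean()) / se
            return qs

        obs = pair_q(data)
        pooled = np.concatenate(data)
        max_qs = []
        for _ in range(4000):
            perm = rng.permutation(pooled)
            max_qs.append(max(pair_q([perm[i * n:(i + 1) * n] for i in range(k)]).values()))
        max_qs = np.asarray(max_qs)
        for r, (i, j) in zip(res, [(0, 1), (0, 2), (1, 2)]):
            p_perm = float((max_qs >= obs[(i, j)]).mean())
            assert r.p_adj == pytest.approx(p_perm, abs=0.025)

    def test_hedges_antisymmetry(self):
        a = GroupSummary("a", 20, 10.0, 2.0)
        b = GroupSummary("b", 30, 8.0, 3.0)
        g_ab, (lo_ab, hi_ab) = hedges_g(a, b)
        g_ba, (lo_ba, hi_ba) = hedges_g(b, a)
        assert g_ab == pytest.approx(-g_ba)
        assert lo_ab == pytest.approx(-hi_ba)

    def test_hedges_identical_groups_zero(self):
        a = GroupSummary("a", 20, 10.0, 2.0)
        assert hedges_g(a, a)[0] == 0.0


class TestHolm:
    def test_monotone_and_bounded(self):
        raw = np.array([0.001, 0.04, 0.03, 0.5, 0.012])
        adj = holm_bonferroni(raw)
        assert np.all(adj >= raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert adj[0] == pytest.approx(0.005)  # smallest raw p times m
        assert np.all(adj <= 1.0)


class TestMixedAnova:
    def random_df(self, rng, k=3, n=10, effect=0.0):
        rows = []
        for g in range(k):
            for i in range(n):
                base = rng.normal(700 + 50 * g, 120)
                rows.append(
                    {
                        "participant_id": f"g{g}_{i}",
                        "group": f"G{g}",
                        "closer": base + rng.normal(effect * (g + 1), 60),
                        "further": base + rng.normal(0, 60),
                    }
                )
        return pd.DataFrame(rows)

    def test_matches_pingouin_on_balanced_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(10):
            df = self.random_df(rng, k=int(rng.integers(2, 5)), n=int(rng.integers(8, 15)), effect=30)
            mine = mixed_anova(df).table.set_index("effect")
            long = df.melt(
                id_vars=["participant_id", "group"],
                value_vars=["closer", "further"],
                var_name="type",
                value_name="dwell",
            )
            ref = pg.mixed_anova(
                data=long, dv="dwell", within="type", subject="participant_id", between="group"
            ).set_index("Source")
            for mine_key, ref_key in [
                ("group", "group"),
                ("type", "type"),
                ("group:type", "Interaction"),
            ]:
                assert mine.loc[mine_key, "F"] == pytest.approx(
                    float(ref.loc[ref_key, "F"]), rel=1e-8
                )

    def test_no_type_effect_when_cells_equal(self):
        rng = np.random.default_rng(8)
        df = self.random_df(rng)
        df["further"] = df["closer"]
        res = mixed_anova(df).table.set_index("effect")
        assert res.loc["type", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["group:type", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_cell_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        df = self.random_df(rng)
        df.loc[0, "closer"] = np.nan
        with pytest.warns(UserWarning):
            res = mixed_anova(df)
        assert res.table.loc[0, "df2"] == len(df) - 1 - df["group"].nunique()

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(10)
        df = self.random_df(rng, k=5, n=12)
        table = mixed_anova(df).table.set_index("effect")
        assert table.loc["group", "df1"] == 4
        assert table.loc["type", "df1"] == 1
        assert np.all(table["df2"] == 60 - 5)


class TestSimpleEffects:
    def test_zero_difference_group(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(12)],
                "group": ["A"] * 6 + ["B"] * 6,
                "closer": rng.normal(700, 100, 12),
            }
        )
        df["further"] = df["closer"]
        df.loc[df["group"] == "B", "further"] = rng.normal(500, 80, 6)
        res = simple_main_effects(df).set_index("group")
        assert res.loc["A", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["A", "mean_diff"] == 0.0
        assert res.loc["B", "p_holm"] >= res.loc["B", "p"]

    def test_paired_t_equivalence(self):
        rng = np.random.default_rng(12)
        a = rng.normal(700, 100, 20)
        b = a - rng.normal(150, 60, 20)
        df = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(20)],
                "group": "A",
                "closer": a,
                "further": b,
            }
        )
        res = simple_main_effects(df).iloc[0]
        t = stats.ttest_rel(a, b)
        assert res["F"] == pytest.approx(t.statistic**2, rel=1e-9)
        assert res["p"] == pytest.approx(t.pvalue, rel=1e-9)
        assert 0 <= res["eta_sq_g"] <= 1


class TestAncova:
    def synthetic(self, rng, n=400, gender_effect=-200.0):
        group = rng.choice(list("abcde"), n)
        gender = rng.choice(["F", "M"], n)
        base = {"a": 1550, "b": 1220, "c": 690, "d": 1330, "e": 1760}
        y = (
            np.array([base[g] for g in group])
            + (gender == "F") * gender_effect
            + rng.normal(0, 400, n)
        )
        return pd.DataFrame(
            {
                "group": group,
                "gender": gender,
                "age": rng.normal(22, 2, n),
                "ses": rng.integers(1, 6, n),
                "mean_focal_dwell_ms": y,
            }
        )

    def test_planted_gender_effect_detected(self):
        df = self.synthetic(np.random.default_rng(13))
        aov = ancova(df, covariates=("gender", "age", "ses"))
        assert aov.loc["gender", "PR(>F)"] < 0.001
        assert 0.01 < aov.loc["gender", "partial_eta_sq"] < 0.2

    def test_noise_covariates_leave_group_F_close(self):
        df = self.synthetic(np.random.default_rng(14), gender_effect=0.0)
        aov_cov = ancova(df, covariates=("age", "ses"))
        aov_none = ancova(df, covariates=())
        F_cov = aov_cov.loc["group", "F"]
        F_none = aov_none.loc["group", "F"]
        assert abs(F_cov - F_none) / F_none < 0.05

    def test_constant_covariate_dropped(self):
        df = self.synthetic(np.random.default_rng(15))
        df["ses"] = 3
        with pytest.warns(UserWarning):
            aov = ancova(df, covariates=("gender", "ses"))
        assert "ses" not in aov.index


class TestAssumptionChecks:
    def test_levene_zero_for_identical_spread(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        F, p = levene_test([base, base + 10])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_levene_detects_gross_heteroscedasticity(self):
        rng = np.random.default_rng(16)
        F, p = levene_test([rng.normal(0, 1, 50), rng.normal(0, 10, 50)])
        assert p < 0.001

    def test_shapiro_on_normal_residuals(self):
        rng = np.random.default_rng(17)
        W, p = shapiro_wilk(rng.normal(size=242))
        assert W > 0.98


class TestPower:
    def test_power_monotone_in_n(self):
        from scipy.stats import f as fdist
        from scipy.stats import ncf

        def achieved(N, f=0.25, k=5, alpha=0.05):
            fc = fdist.ppf(1 - alpha, k - 1, N - k)
            return ncf.sf(fc, k - 1, N - k, f**2 * N)

        powers = [achieved(N) for N in range(50, 400, 25)]
        assert np.all(np.diff(powers) > 0)

    def test_matches_exhaustive_scan_for_large_effect(self):
        spec = power_min_n(1.0, 0.05, 0.80, 2)
        # independent oracle: brute-force scan of every even total N
        from scipy.stats import f as fdist
        from scipy.stats import ncf

        for N in range(4, 200, 2):
            fc = fdist.ppf(0.95, 1, N - 2)
            if ncf.sf(fc, 1, N - 2, 1.0 * N) >= 0.80:
                assert spec.min_total_n == N
                break
        assert spec.min_per_group_n * 2 == spec.min_total_n

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            power_min_n(0.0)
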