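"""Statistical machinery: hand-computed oracles, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from yszkit import stats, synth
from yszkit.cli import combine_depths


class TestFieldZscore:
    def test_one_two_three(self):
        t = pd.DataFrame({"field_id": ["f"] * 3, "v": [1.0, 2.0, 3.0]})
        out = stats.field_zscore(t, ["v"])
        np.testing.assert_allclose(out["z_v"], [-1.0, 0.0, 1.0])

    def test_constant_field_gives_missing(self):
        t = pd.DataFrame({"field_id": ["f"] * 3 + ["g"] * 3,
                          "v": [5.0, 5.0, 5.0, 1.0, 2.0, 3.0]})
        out = stats.field_zscore(t, ["v"])
        assert out["z_v"].iloc[:3].isna().all()
        assert not out["z_v"].iloc[3:].isna().any()

    def test_per_field_centering_identity(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"field_id": np.repeat(list("abc"), 20),
                          "v": rng.normal(5, 2, 60)})
        out = stats.field_zscore(t, ["v"])
        g = out.groupby("field_id")["z_v"]
        np.testing.assert_allclose(g.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(g.std(), 1.0, atol=1e-9)

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="nope"):
            stats.field_zscore(pd.DataFrame({"field_id": ["f"]}), ["nope"])


class TestCorrelationMatrix:
    def test_self_and_antisymmetric(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        t = pd.DataFrame({"x": x, "y": x, "neg": -x})
        m = stats.correlation_matrix(t, ["x", "y", "neg"])
        assert m["r"].loc["x", "y"] == pytest.approx(1.0)
        assert m["r"].loc["x", "neg"] == pytest.approx(-1.0)
        assert m["r2"].loc["x", "neg"] == pytest.approx(1.0)

    def test_perfect_linear_relation(self):
        t = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10]})
        m = stats.correlation_matrix(t, ["a", "b"])
        assert m["r"].loc["a", "b"] == pytest.approx(1.0)

    def test_constant_variable_missing(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "c": [7.0] * 4})
        m = stats.correlation_matrix(t, ["a", "c"])
        assert np.isnan(m["r"].loc["a", "c"])

    def test_star_thresholds(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        t = pd.DataFrame({"x": x, "strong": x + rng.normal(0, 0.3, n),
                          "noise": rng.normal(size=n)})
        m = stats.correlation_matrix(t, ["x", "strong", "noise"])
        assert m["stars"].loc["x", "strong"] == "***"
        p = m["p"].loc["x", "noise"]
        want = "" if p > 0.05 else "*"
        assert m["stars"].loc["x", "noise"] == want


class TestStepwiseMLR:
    def test_exact_signal_selected_with_coefficient(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=100)
        x2 = rng.normal(size=100)
        t = pd.DataFrame({"y": 2.0 * x1, "x1": x1, "x2": x2})
        res = stats.stepwise_mlr(t, "y", ["x1", "x2"])
        assert res.selected == ["x1"]
        assert res.params["x1"] == pytest.approx(2.0, abs=1e-8)

    def test_null_response_selection_matches_aic_theory(self):
        """With a pure-noise response, AIC admits each spurious candidate
        with probability P(chi2_1 > 2) ~ 0.157, so the intercept-only model
        is selected in (1 - 0.157)^3 ~ 60% of replicates."""
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            t = pd.DataFrame({
                "y": rng.normal(size=200),
                "a": rng.normal(size=200),
                "b": rng.normal(size=200),
                "c": rng.normal(size=200),
            })
            res = stats.stepwise_mlr(t, "y", ["a", "b", "c"])
            hits += res.selected == []
        assert 20 <= hits <= 40  # 0.599 +- sampling error over 50 replicates

    def test_collinear_candidate_dropped(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        t = pd.DataFrame({"y": x + rng.normal(0, 0.1, 50), "x": x, "x_dup": 2 * x})
        res = stats.stepwise_mlr(t, "y", ["x", "x_dup"])
        assert "x_dup" not in res.selected

    def test_recovers_generator_regional_model(self):
        """Selected model includes clay and MAT with the configured signs in
        >= 90% of replicate studies."""
        hits = 0
        for s in range(50):
            study = synth.StudyConfig(fields=synth.default_study_fields(s))
            t = synth.generate_study(study, seed=s, mode="stats")
            comb = combine_depths(t)
            res = stats.stepwise_mlr(comb, "soc_pct", ["clay_pct", "mat", "map_mm"])
            hits += ("clay_pct" in res.selected and "mat" in res.selected
                     and res.params["clay_pct"] > 0 and res.params["mat"] < 0)
        assert hits >= 45


class TestAnovaTukey:
    def test_null_identical_groups(self):
        t = pd.DataFrame({"g": list("aabb"), "v": [1.0, 2.0, 1.0, 2.0]})
        res = stats.anova_tukey(t, "v", "g")
        assert res.F == pytest.approx(0.0)
        assert res.eta_squared == pytest.approx(0.0)

    def test_hand_decomposition_123_456(self):
        t = pd.DataFrame({"g": list("aaabbb"), "v": [1, 2, 3, 4, 5, 6.0]})
        res = stats.anova_tukey(t, "v", "g")
        assert res.F == pytest.approx(13.5)
        assert res.eta_squared == pytest.approx(13.5 / 17.5)
        assert res.df_between == 1 and res.df_within == 4

    def test_two_group_tukey_equals_studentized_range_ci(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"g": np.repeat(["a", "b"], 12),
                          "v": np.concatenate([rng.normal(0, 1, 12),
                                               rng.normal(1, 1, 12)])})
        res = stats.anova_tukey(t, "v", "g")
        a = t.v[:12].to_numpy(); b = t.v[12:].to_numpy()
        diff = b.mean() - a.mean()
        sp2 = (a.var(ddof=1) * 11 + b.var(ddof=1) * 11) / 22
        q = sps.studentized_range.ppf(0.95, 2, 22)
        half = q / np.sqrt(2) * np.sqrt(sp2 * (1 / 12 + 1 / 12))
        row = res.tukey.iloc[0]
        assert row["diff"] == pytest.approx(diff, abs=1e-8)
        assert row["ci_low"] == pytest.approx(diff - half, abs=1e-6)
        assert row["ci_high"] == pytest.approx(diff + half, abs=1e-6)

    def test_tukey_p_at_least_unadjusted(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame({"g": np.repeat(list("abcd"), 15),
                          "v": rng.normal(np.repeat([0, 0.3, 0.6, 1.0], 15), 1)})
        res = stats.anova_tukey(t, "v", "g")
        for _, row in res.tukey.iterrows():
            a = t.loc[t.g == row["a"], "v"]
            b = t.loc[t.g == row["b"], "v"]
            _, p_raw = sps.ttest_ind(a, b)
            assert row["p_adj"] >= p_raw - 1e-9

    def test_eta_squared_equals_r2_for_two_groups(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame({"g": np.repeat(["a", "b"], 20),
                          "v": rng.normal(np.repeat([0, 0.8], 20), 1)})
        res = stats.anova_tukey(t, "v", "g")
        r = sps.pearsonr((t.g == "b").astype(float), t.v).statistic
        assert res.eta_squared == pytest.approx(r**2, abs=1e-10)

    def test_small_group_named_in_error(self):
        t = pd.DataFrame({"g": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="b"):
            stats.anova_tukey(t, "v", "g")


class TestBootstrapPower:
    def test_overwhelming_effect_gives_power_one(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame({"g": np.repeat(list("abcd"), 30),
                          "v": rng.normal(np.repeat([0, 10, 20, 30], 30), 1)})
        res = stats.bootstrap_power(t, "v", "g", n_iter=200, seed=1)
        assert res["power"] == pytest.approx(1.0)

    def test_deterministic_per_seed(self, null_group_table):
        a = stats.bootstrap_power(null_group_table, "value", "zone",
                                  n_iter=500, seed=3)
        b = stats.bootstrap_power(null_group_table, "value", "zone",
                                  n_iter=500, seed=3)
        assert a["power"] == b["power"]

    def test_null_optimism_is_bounded(self):
        """Post-hoc bootstrap power inherits the observed noise effect, so
        under an exact null its mean sits above alpha (known optimism of
        retrospective power) but well below the power at any real effect."""
        powers = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            t = pd.DataFrame({"g": np.repeat(list("abcd"), 30),
                              "v": rng.standard_normal(120)})
            powers.append(stats.bootstrap_power(t, "v", "g", n_iter=500,
                                                seed=s)["power"])
        assert 0.05 <= np.mean(powers) <= 0.5

    def test_monotone_in_effect_size(self):
        means = []
        for effect in (0.0, 0.5, 1.5):
            p = []
            for s in range(20):
                rng = np.random.default_rng(s)
                t = pd.DataFrame({
                    "g": np.repeat(list("abcd"), 15),
                    "v": rng.normal(np.repeat([0, 0, 0, effect], 15), 1),
                })
                p.append(stats.bootstrap_power(t, "v", "g", n_iter=300,
                                               seed=s)["power"])
            means.append(np.mean(p))
        assert means[0] <= means[1] <= means[2]


class TestManagementContrast:
    def make_table(self, deltas):
        rows = []
        for f, (flag, d) in enumerate(deltas):
            for depth in (0.0, 15.0):
                for zone, val in (("HS", d / 2), ("LS", -d / 2), ("MS", 0.0)):
                    for core in range(2):
                        rows.append({"field_id": f"f{f}", "zone": zone,
                                     "depth_top_cm": depth, "till": flag,
                                     "z": val})
        return pd.DataFrame(rows)

    def test_all_identical_zones_give_zero(self):
        t = self.make_table([(True, 0.0), (False, 0.0)])
        out = stats.management_contrast(t, "z", "till")
        np.testing.assert_allclose(out["mean_diff"], 0.0)

    def test_group_means_by_flag(self):
        t = self.make_table([(True, 1.0), (True, 1.0), (False, 0.2)])
        out = stats.management_contrast(t, "z", "till")
        got = out.set_index(["till", "depth_top_cm"])["mean_diff"]
        assert got[(True, 0.0)] == pytest.approx(1.0)
        assert got[(False, 0.0)] == pytest.approx(0.2)

    def test_single_flag_level_reported_alone(self):
        t = self.make_table([(True, 0.5), (True, 0.7)])
        out = stats.management_contrast(t, "z", "till")
        assert set(out["till"]) == {True}

    def test_field_missing_zone_excluded(self):
        t = self.make_table([(True, 1.0), (False, 0.4)])
        t = t[~((t.field_id == "f0") & (t.zone == "HS"))]
        out = stats.management_contrast(t, "z", "till")
        assert set(out["till"]) == {False}

    def test_recovers_configured_no_till_amplification(self):
        """A +0.4 SD no-till surface shift in the generator is recovered
        within +-0.15 as the no-till minus tilled contrast difference."""
        diffs = []
        for s in range(50):
            profile = synth.ZoneEffectProfile(
                management_shift={"no_till": (0.4, 0.0)})
            study = synth.StudyConfig(fields=synth.default_study_fields(s),
                                      profile=profile)
            t = synth.generate_study(study, seed=s, mode="stats")
            t = stats.field_zscore(t, ["soc_pct"])
            out = stats.management_contrast(t, "z_soc_pct", "tillage")
            surf = out[out.depth_top_cm == 0.0].set_index("tillage")["mean_diff"]
            # tillage=False is the no-till group
            diffs.append(surf[False] - surf[True])
        assert abs(np.mean(diffs) - 0.4) <= 0.15
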