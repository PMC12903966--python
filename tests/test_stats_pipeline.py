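"""Group comparisons, correlations, random-forest importance, path analysis."""

import numpy as np
import pandas as pd
import pytest

from stoichlim import (AnalysisError, compact_letter_display,
                       correlation_network, group_compare, path_model,
                       restoration_correlation, rf_importance)
from tests._oracles import pearson_by_formula, permutation_anova_p


def toy_cohort(groups: dict[str, np.ndarray], variable="y", depth="0-15"):
    rows = []
    for treatment, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"plot_id": f"{treatment}-{i}", "treatment": treatment,
                         "depth_cm": depth, variable: v})
    return pd.DataFrame(rows)


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["a1", "a2", "a3"], set())
        assert set(letters.values()) == {"a"}

    def test_one_outlier_group(self):
        letters = compact_letter_display(
            ["d", "p", "a"], {("a", "d"), ("a", "p")})
        assert set(letters["a"]) & set(letters["d"]) == set()
        assert set(letters["p"]) & set(letters["d"])

    def test_chain_pattern_is_transitive_consistent(self):
        # g1 != g3 only: g2 must share a letter with both ends
        letters = compact_letter_display(["g1", "g2", "g3"], {("g1", "g3")})
        assert not set(letters["g1"]) & set(letters["g3"])
        assert set(letters["g2"]) & set(letters["g1"])
        assert set(letters["g2"]) & set(letters["g3"])


class TestGroupCompare:
    def test_null_case_groups_share_letter(self):
        rng = np.random.default_rng(11)
        data = toy_cohort({t: rng.normal(10, 1, 6) for t in
                           ("degraded", "passive", "active")})
        comp = group_compare(data, "y", depth="0-15")
        letters = comp.summary["letter_group"]
        assert set.intersection(*(set(l) for l in letters))

    def test_overwhelming_effect_separates_third_group(self):
        rng = np.random.default_rng(5)
        data = toy_cohort({
            "degraded": rng.normal(1, 0.05, 3),
            "passive": rng.normal(1, 0.05, 3),
            "active": rng.normal(100, 5, 3),
        })
        comp = group_compare(data, "y", depth="0-15")
        letters = dict(zip(comp.summary["treatment"], comp.summary["letter_group"]))
        assert not set(letters["active"]) & set(letters["degraded"])
        assert set(letters["passive"]) & set(letters["degraded"])
        # permutation oracle agrees the effect is extreme
        groups = [data.loc[data.treatment == t, "y"].to_numpy()
                  for t in ("degraded", "passive", "active")]
        assert permutation_anova_p(groups, n_perm=20_000, seed=0) < 0.01
        assert comp.anova_p < 0.01

    def test_anova_p_matches_permutation_oracle(self):
        """Parametric p within Monte-Carlo distance of a permutation-F null
        on a moderate fixed table."""
        rng = np.random.default_rng(321)
        groups = {t: rng.normal(m, 1.0, 15) for t, m in
                  (("degraded", 10.0), ("passive", 10.45), ("active", 10.2))}
        comp = group_compare(toy_cohort(groups), "y", depth="0-15")
        oracle = permutation_anova_p(list(groups.values()), n_perm=100_000, seed=1)
        assert 0.02 < comp.anova_p < 0.98  # non-degenerate regime
        assert abs(comp.anova_p - oracle) <= 0.01

    def test_sqrt_transform_triggered_by_skew(self):
        rng = np.random.default_rng(3)
        data = toy_cohort({
            "degraded": rng.lognormal(0, 1.4, 12) ** 2,
            "passive": rng.lognormal(0.2, 1.4, 12) ** 2,
            "active": rng.lognormal(0.4, 1.4, 12) ** 2,
        })
        comp = group_compare(data, "y", depth="0-15")
        assert comp.shapiro_p < 0.05 and comp.sqrt_transformed
        forced = group_compare(data, "y", depth="0-15", transform="none")
        assert not forced.sqrt_transformed

    def test_zero_variance_everywhere_reports_no_difference(self):
        data = toy_cohort({t: np.full(3, 7.0) for t in ("degraded", "active")})
        comp = group_compare(data, "y", depth="0-15")
        assert comp.anova_p == 1.0
        assert set(comp.summary["letter_group"]) == {"a"}

    def test_single_replicate_rejected(self):
        data = toy_cohort({"degraded": np.array([1.0]),
                           "active": np.array([2.0, 3.0])})
        with pytest.raises(AnalysisError, match="replicates"):
            group_compare(data, "y", depth="0-15")

    def test_percent_change_column(self):
        data = toy_cohort({"degraded": np.full(3, 30.8),
                           "active": np.full(3, 44.4)})
        comp = group_compare(data, "y", depth="0-15")
        row = comp.summary.set_index("treatment")
        assert row.loc["active", "pct_change_vs_degraded"] == 44
        assert row.loc["degraded", "pct_change_vs_degraded"] == 0


class TestCorrelations:
    def test_exact_linear_relation(self):
        x = np.arange(1.0, 11.0)
        data = pd.DataFrame({"treatment": "degraded", "x": x, "y": 2 * x})
        edges, _ = correlation_network(data, ["x", "y"])
        assert edges.loc[0, "r"] == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame({"treatment": "degraded",
                             "x": rng.normal(size=30),
                             "y": rng.normal(size=30)})
        edges, _ = correlation_network(data, ["x", "y"])
        assert edges.loc[0, "r"] == pytest.approx(
            pearson_by_formula(data["x"].to_numpy(), data["y"].to_numpy()))

    def test_independent_pairs_mostly_uncorrelated(self):
        rng = np.random.default_rng(99)
        small = 0
        reps = 200
        for _ in range(reps):
            r = pearson_by_formula(rng.normal(size=1000), rng.normal(size=1000))
            small += abs(r) < 0.1
        assert small / reps >= 0.95

    def test_constant_variable_omitted_with_log(self):
        data = pd.DataFrame({"treatment": "degraded",
                             "x": np.arange(5.0), "c": np.ones(5)})
        edges, omitted = correlation_network(data, ["x", "c"])
        assert edges.empty and "c" in omitted[0]

    def test_point_biserial_restoration_indicator(self):
        data = pd.DataFrame({
            "treatment": ["degraded"] * 4 + ["active"] * 4,
            "v": [1.0, 1.1, 0.9, 1.0, 3.0, 3.2, 2.9, 3.1],
        })
        res = restoration_correlation(data, ["v"], "active")
        indicator = np.array([0.0] * 4 + [1.0] * 4)
        assert res.loc[0, "r"] == pytest.approx(
            pearson_by_formula(data["v"].to_numpy(), indicator))
        assert res.loc[0, "r"] > 0.9


class TestRandomForest:
    @staticmethod
    def planted(seed, n=200):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rng.normal(size=n)                      # pure noise
        y = 2.0 * a + rng.normal(scale=0.5, size=n)
        return pd.DataFrame({"a": a, "b": b, "y": y})

    def test_planted_signal_recovered_noise_not_flagged(self):
        """Signal predictor ranks first and is significant; the pure-noise
        predictor stays inside its response-permutation null."""
        data = self.planted(17, n=150)
        res = rf_importance(data, "y", ["a", "b"], n_trees=200, seed=17,
                            n_null=49)
        table = res.table.set_index("predictor")
        assert table.loc["a", "pct_inc_mse"] > table.loc["b", "pct_inc_mse"]
        assert table.loc["a", "significant"]
        assert not table.loc["b", "significant"]

    def test_constant_response_gives_zero_importance(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30),
                             "y": np.full(30, 3.0)})
        res = rf_importance(data, "y", ["a", "b"], n_trees=100, seed=2, n_null=19)
        assert (res.table["pct_inc_mse"].abs() < 1e-9).all()
        assert not res.table["significant"].any()

    def test_reproducible_with_fixed_seed(self):
        data = self.planted(4)
        r1 = rf_importance(data, "y", ["a", "b"], n_trees=100, seed=9, n_null=9)
        r2 = rf_importance(data, "y", ["a", "b"], n_trees=100, seed=9, n_null=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_duplicated_predictor_shares_importance_mass(self):
        data = self.planted(23)
        data["a2"] = data["a"]
        solo = rf_importance(data, "y", ["a", "b"], n_trees=300, seed=23, n_null=0)
        dup = rf_importance(data, "y", ["a", "a2", "b"], n_trees=300, seed=23,
                            n_null=0)
        solo_t = solo.table.set_index("predictor")
        dup_t = dup.table.set_index("predictor")
        # the copies split the signal but the noise column stays last
        assert dup_t.index[-1] == "b" or dup_t.loc["b", "pct_inc_mse"] < min(
            dup_t.loc["a", "pct_inc_mse"], dup_t.loc["a2", "pct_inc_mse"])
        assert solo_t.index[0] == "a"

    def test_too_few_observations_rejected(self):
        data = self.planted(1, n=4)
        with pytest.raises(AnalysisError):
            rf_importance(data, "y", ["a", "b"])


class TestPathModel:
    @staticmethod
    def chain_data(seed=0, n=500, noise=0.3):
        rng = np.random.default_rng(seed)

        def child(parent, beta):
            raw = beta * (parent - parent.mean()) / parent.std(ddof=1)
            return raw + rng.normal(scale=noise, size=len(parent))

        angle = rng.normal(size=n)
        cue = child(angle, -0.6)
        poc = child(cue, -0.6)
        maoc = child(poc, 0.6)
        soc = child(maoc, 0.6)
        return pd.DataFrame({"angle": angle, "cue": cue, "poc": poc,
                             "maoc": maoc, "soc": soc})

    EDGES = [("angle", "cue"), ("cue", "poc"), ("poc", "maoc"), ("maoc", "soc")]

    def test_single_edge_reduces_to_pearson_r(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        data = pd.DataFrame({"x": x, "y": y})
        fit = path_model(data, [("x", "y")])
        assert fit.edges.loc[0, "coefficient"] == pytest.approx(
            pearson_by_formula(x, y))
        assert fit.df == 0 and fit.chi_square == pytest.approx(0.0, abs=1e-9)

    def test_sign_recovery_on_chain(self):
        fit = path_model(self.chain_data(seed=6), self.EDGES)
        signs = {(r.source, r.target): np.sign(r.coefficient)
                 for r in fit.edges.itertuples()}
        assert signs[("angle", "cue")] == -1
        assert signs[("cue", "poc")] == -1
        assert signs[("poc", "maoc")] == 1
        assert signs[("maoc", "soc")] == 1
        assert all(abs(c) <= 1.0 + 1e-9 for c in fit.edges["coefficient"])
        assert 0 < min(fit.r2.values()) and max(fit.r2.values()) < 1

    def test_total_effect_equals_product_along_chain(self):
        fit = path_model(self.chain_data(seed=6), self.EDGES)
        coef = {(r.source, r.target): r.coefficient for r in fit.edges.itertuples()}
        product = (coef[("angle", "cue")] * coef[("cue", "poc")]
                   * coef[("poc", "maoc")] * coef[("maoc", "soc")])
        total = fit.total_effects.set_index(["source", "target"])
        assert total.loc[("angle", "soc"), "total_effect"] == pytest.approx(product)

    def test_chain_model_consistent_with_its_own_data(self):
        fit = path_model(self.chain_data(seed=12), self.EDGES)
        assert fit.df == 6
        assert fit.consistent  # chi-square p > 0.05 on generating-model data

    def test_cycle_rejected(self):
        with pytest.raises(AnalysisError, match="cycle"):
            path_model(self.chain_data(), [("angle", "cue"), ("cue", "angle")])

    def test_collinear_parents_rejected(self):
        data = self.chain_data(seed=3)
        data["cue_copy"] = data["cue"]
        with pytest.raises(AnalysisError, match="singular|collinear"):
            path_model(data, [("cue", "poc"), ("cue_copy", "poc")])
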