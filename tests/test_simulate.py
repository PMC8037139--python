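"""Scenario construction, data generation, and study metrics."""

import numpy as np
import pandas as pd
import pytest

import bgindex as bg


class TestBuildScenario:
    def test_set_d_level3_moderate(self):
        sc = bg.build_scenario("D", 3, "moderate")
        np.testing.assert_allclose(sc.true_ors, [1 / 1.5, 1.5, 1.5])
        assert sc.n == 500
        np.testing.assert_allclose(sc.true_weights[0],
                                   [1 / 3, 1 / 3, 1 / 3, 0, 0])
        np.testing.assert_allclose(sc.true_weights[1], [0.5, 0.5, 0, 0])

    def test_null_scenario_all_or_one(self):
        sc = bg.build_scenario("A", 1, "weak")
        np.testing.assert_allclose(sc.true_ors, 1.0)
        assert sc.n == 1000
        assert sc.group_sizes == (5, 4)

    def test_set_b_single_important_per_group(self):
        sc = bg.build_scenario("B", 4, "strong")
        for w in sc.true_weights:
            assert (w == 1.0).sum() == 1
            assert (w == 0.0).sum() == len(w) - 1

    def test_set_a_strength_progression(self):
        # positive group ORs 1.5/2.0/2.5/3.0 with reciprocal negatives
        for level, pos in zip((2, 3, 4, 5), (1.5, 2.0, 2.5, 3.0)):
            sc = bg.build_scenario("A", level, "weak")
            np.testing.assert_allclose(sc.true_ors, [1 / pos, pos])

    def test_set_d_small_effect_progression(self):
        for level, pos in zip((2, 3, 4, 5), (1.25, 1.5, 1.75, 2.0)):
            sc = bg.build_scenario("D", level, "weak")
            np.testing.assert_allclose(sc.true_ors,
                                       [1 / pos, pos, pos])

    def test_intercept_centers_linear_predictor(self):
        sc = bg.build_scenario("C", 5, "weak")
        assert sc.true_beta0 == pytest.approx(
            -1.5 * sc.true_betas.sum())

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            bg.build_scenario("E", 1, "weak")
        with pytest.raises(ValueError):
            bg.build_scenario("A", 6, "weak")
        with pytest.raises(ValueError):
            bg.build_scenario("A", 1, "medium")


class TestCorrelationSpec:
    def test_stated_structures(self):
        assert bg.CORRELATIONS["weak"] == bg.CorrelationSpec(0.5, 0.1)
        assert bg.CORRELATIONS["moderate"] == bg.CorrelationSpec(0.7, 0.3)
        assert bg.CORRELATIONS["strong"] == bg.CorrelationSpec(0.9, 0.5)

    def test_matrix_blocks(self):
        R = bg.CorrelationSpec(0.7, 0.3).matrix([2, 2])
        expect = np.array([[1.0, 0.7, 0.3, 0.3],
                           [0.7, 1.0, 0.3, 0.3],
                           [0.3, 0.3, 1.0, 0.7],
                           [0.3, 0.3, 0.7, 1.0]])
        np.testing.assert_allclose(R, expect)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            bg.CorrelationSpec(0.1, 0.9).matrix([3, 3])


class TestGenerateExposures:
    def test_empirical_correlations_converge(self):
        sc = bg.build_scenario("D", 1, "moderate", n=50000)
        table = bg.generate_exposures(sc, 21)
        R = np.corrcoef(table.values.T)
        within = R[0, 1]   # both in group 1
        across = R[0, 6]   # group 1 vs group 2
        assert within == pytest.approx(0.7, abs=0.02)
        assert across == pytest.approx(0.3, abs=0.02)

    def test_standard_normal_marginals(self):
        sc = bg.build_scenario("D", 1, "weak", n=50000)
        table = bg.generate_exposures(sc, 22)
        np.testing.assert_allclose(table.values.mean(axis=0), 0.0, atol=0.03)
        np.testing.assert_allclose(table.values.std(axis=0), 1.0, atol=0.03)

    def test_seeded_determinism(self):
        sc = bg.build_scenario("D", 1, "weak", n=100)
        a = bg.generate_exposures(sc, 23)
        b = bg.generate_exposures(sc, 23)
        np.testing.assert_array_equal(a.values, b.values)


class TestGenerateOutcome:
    def test_null_gives_exactly_half_probability(self):
        sc = bg.build_scenario("D", 1, "weak", n=2000)
        assert sc.true_beta0 == 0.0
        # eta = 0 for every subject, so p = 0.5 exactly; the draw must land
        # in the case band quickly
        data = bg.generate_dataset(sc, 31)
        assert 0.4 <= data.y.mean() <= 0.6

    def test_case_fraction_always_in_band(self):
        sc = bg.build_scenario("D", 5, "strong")
        for seed in range(5):
            data = bg.generate_dataset(sc, seed)
            assert 0.4 <= data.y.mean() <= 0.6

    def test_logistic_refit_recovers_true_betas(self):
        import statsmodels.api as sm
        sc = bg.build_scenario("D", 3, "moderate", n=50000)
        data = bg.generate_dataset(sc, 32)
        idx = bg.compute_indices(data.quantiles, sc.groups, sc.true_weights)
        fit = sm.Logit(data.y, sm.add_constant(idx)).fit(disp=0)
        np.testing.assert_allclose(fit.params[1:], sc.true_betas, atol=0.05)
        assert fit.params[0] == pytest.approx(sc.true_beta0, abs=0.1)

    def test_miscalibrated_intercept_raises(self):
        sc = bg.build_scenario("D", 1, "weak", n=3000)
        sc2 = bg.SimulationScenario(
            scenario_set="D", strength_level=1, correlation="weak",
            n=3000, group_sizes=sc.group_sizes, true_ors=sc.true_ors,
            true_weights=sc.true_weights)
        # force an absurd intercept through a subclassed property
        class Bad(bg.SimulationScenario):
            @property
            def true_beta0(self):
                return 10.0
        bad = Bad(scenario_set="D", strength_level=1, correlation="weak",
                  n=3000, group_sizes=sc.group_sizes, true_ors=sc.true_ors,
                  true_weights=sc.true_weights)
        q = bg.quantize_exposures(bg.generate_exposures(bad, 0), Q=4)
        with pytest.raises(RuntimeError, match="miscalibrated"):
            bg.generate_outcome(bad, q, 0, max_retries=5)


class TestRunReplicates:
    def test_bookkeeping_and_determinism(self):
        sc = bg.build_scenario("D", 3, "weak", n=250)
        kw = dict(n_reps=2, methods=("bayes",), seed=5,
                  n_iter=500, n_burnin=150)
        a = bg.run_replicates(sc, **kw)
        assert len(a.effects) == 2 * 1 * 3
        assert len(a.weights) == 2 * 1 * 14
        assert a.failures.empty
        b = bg.run_replicates(sc, **kw)
        pd.testing.assert_frame_equal(a.effects, b.effects)

    def test_both_methods_record_all_groups(self):
        sc = bg.build_scenario("D", 3, "weak", n=250)
        res = bg.run_replicates(
            sc, n_reps=2, methods=("bayes", "gwqs"), seed=6,
            n_iter=500, n_burnin=150,
            gwqs_config=bg.GWQSConfig(n_bootstrap=5, n_starts=1))
        assert len(res.effects) == 2 * 2 * 3
        assert set(res.effects["method"]) == {"bayes", "gwqs"}

    def test_unknown_method_rejected(self):
        sc = bg.build_scenario("D", 1, "weak")
        with pytest.raises(ValueError, match="unknown"):
            bg.run_replicates(sc, n_reps=1, methods=("bayes", "lasso"))


def fixture_effects():
    return pd.DataFrame({
        "replicate": [0, 1, 2] * 2,
        "method": ["bayes"] * 3 + ["gwqs"] * 3,
        "group": ["g1"] * 6,
        "true_or": [1.5] * 6,
        "est_or": [1.4, 1.6, 1.5, 1.2, 1.8, 1.5],
        "ci_lower": [1.2, 0.8, 1.1, 0.9, 1.1, 0.7],
        "ci_upper": [2.0, 1.5, 1.9, 1.6, 2.4, 1.2],
    })


class TestMetrics:
    def test_power_counting(self):
        eff = fixture_effects()
        out = bg.compute_power(eff).set_index("method")
        assert out.loc["bayes", "power"] == pytest.approx(2 / 3)
        assert out.loc["gwqs", "power"] == pytest.approx(1 / 3)

    def test_power_zero_when_all_cover(self):
        eff = fixture_effects()
        eff["ci_lower"], eff["ci_upper"] = 0.5, 2.0
        assert (bg.compute_power(eff)["power"] == 0).all()

    def test_power_matches_hand_count_on_fixture(self, rng):
        rows = []
        for rep in range(10):
            lo = rng.uniform(0.5, 1.2)
            rows.append({"replicate": rep, "method": "bayes", "group": "g",
                         "true_or": 2.0, "est_or": 1.0,
                         "ci_lower": lo, "ci_upper": lo + rng.uniform(0, 1)})
        eff = pd.DataFrame(rows)
        hand = sum((r["ci_lower"] > 1) or (r["ci_upper"] < 1)
                   for r in rows) / 10
        assert bg.compute_power(eff)["power"].iloc[0] == pytest.approx(hand)

    def test_bias_mse_trivial_cases(self):
        eff = fixture_effects().query("method == 'bayes'").copy()
        eff["est_or"] = eff["true_or"]
        out = bg.compute_bias_mse(eff)
        assert out["bias"].iloc[0] == 0.0 and out["mse"].iloc[0] == 0.0
        eff["est_or"] = [1.5 + 0.1, 1.5 - 0.1, 1.5 + 0.1]
        out = bg.compute_bias_mse(eff)
        assert out["bias"].iloc[0] == pytest.approx(0.1 / 3)
        delta = np.array([0.1, -0.1, 0.1])
        assert out["mse"].iloc[0] == pytest.approx((delta ** 2).mean())

    def test_bias_mse_matches_loop_oracle(self, rng):
        eff = fixture_effects()
        out = bg.compute_bias_mse(eff).set_index("method")
        for method in ("bayes", "gwqs"):
            sub = eff[eff["method"] == method]
            errs = [e - t for e, t in zip(sub["est_or"], sub["true_or"])]
            assert out.loc[method, "bias"] == pytest.approx(
                np.mean(errs))
            assert out.loc[method, "mse"] == pytest.approx(
                np.mean(np.square(errs)))

    def test_bias_mse_log_scale_option(self):
        eff = fixture_effects()
        out = bg.compute_bias_mse(eff, scale="log")
        sub = eff[eff["method"] == "bayes"]
        expect = np.mean(np.log(sub["est_or"]) - np.log(sub["true_or"]))
        assert out.set_index("method").loc["bayes", "bias"] == \
            pytest.approx(expect)

    def test_sens_spec_perfect_estimates(self):
        sc = bg.build_scenario("D", 3, "weak")
        rows = []
        for chem, w, thr in zip(
                sc.chemical_ids, np.concatenate(sc.true_weights),
                np.concatenate([np.full(c, 1 / c) for c in sc.group_sizes])):
            rows.append({"replicate": 0, "method": "bayes",
                         "chemical": chem, "group": "g", "weight": w,
                         "true_weight": w, "threshold": thr,
                         "truly_important": w > 0})
        out = bg.compute_sensitivity_specificity(pd.DataFrame(rows))
        assert out["sensitivity"].iloc[0] == 1.0
        assert out["specificity"].iloc[0] == 1.0

    def test_sens_spec_uniform_weights_boundary(self):
        # uniform estimated weights sit exactly at 1/C: every chemical is
        # called important (boundary inclusive), so sens 1 and spec 0
        wdf = pd.DataFrame({
            "replicate": 0, "method": "bayes",
            "chemical": [f"c{i}" for i in range(4)],
            "group": "g", "weight": 0.25, "true_weight": [0.5, 0.5, 0, 0],
            "threshold": 0.25, "truly_important": [True, True, False, False],
        })
        out = bg.compute_sensitivity_specificity(wdf)
        assert out["sensitivity"].iloc[0] == 1.0
        assert out["specificity"].iloc[0] == 0.0

    def test_sens_spec_matches_confusion_matrix_oracle(self, rng):
        n = 40
        wdf = pd.DataFrame({
            "replicate": np.repeat(np.arange(10), 4),
            "method": "bayes",
            "chemical": list("abcd") * 10,
            "group": "g",
            "weight": rng.uniform(0, 0.6, size=n),
            "true_weight": 0.0,
            "threshold": 0.25,
            "truly_important": rng.random(n) < 0.5,
        })
        out = bg.compute_sensitivity_specificity(wdf)
        called = wdf["weight"] >= 0.25
        tp = (called & wdf["truly_important"]).sum()
        fn = (~called & wdf["truly_important"]).sum()
        tn = (~called & ~wdf["truly_important"]).sum()
        fp = (called & ~wdf["truly_important"]).sum()
        assert out["sensitivity"].iloc[0] == pytest.approx(tp / (tp + fn))
        assert out["specificity"].iloc[0] == pytest.approx(tn / (tn + fp))


class TestSummaries:
    def test_effect_summary_point_mass(self):
        import bgindex.results as results
        row = results._or_row("g", "group", np.full(100, np.log(2.0)))
        assert row["odds_ratio"] == pytest.approx(2.0)
        assert row["ci_lower"] == pytest.approx(2.0)
        assert row["ci_upper"] == pytest.approx(2.0)
        assert row["significant"]

    def test_effect_summary_lognormal_interval(self, rng):
        draws = rng.normal(0, 0.5, size=200000)
        row = __import__("bgindex.results", fromlist=["_or_row"])._or_row(
            "g", "group", draws)
        assert row["ci_lower"] == pytest.approx(np.exp(-1.96 * 0.5), rel=0.03)
        assert row["ci_upper"] == pytest.approx(np.exp(1.96 * 0.5), rel=0.03)

    def test_quantiles_match_sort_oracle(self, rng):
        draws = rng.normal(size=4001)
        row = __import__("bgindex.results", fromlist=["_or_row"])._or_row(
            "g", "group", draws)
        srt = np.sort(np.exp(draws))
        lo = np.quantile(srt, 0.025)
        hi = np.quantile(srt, 0.975)
        assert row["ci_lower"] == pytest.approx(lo, rel=1e-12)
        assert row["ci_upper"] == pytest.approx(hi, rel=1e-12)

    def test_classify_important_boundary_inclusive(self):
        wdf = pd.DataFrame({"chemical": ["a", "b"], "group": ["g", "g"],
                            "weight": [0.20, 0.24],
                            "threshold": [0.20, 0.25]})
        flags = bg.classify_important(wdf)
        assert flags.tolist() == [True, False]

    def test_forest_plot_data_preserves_order_and_null_line(self):
        eff = pd.DataFrame({
            "variable": [f"v{i}" for i in range(6)],
            "kind": "group",
            "odds_ratio": np.linspace(0.5, 2, 6),
            "ci_lower": np.linspace(0.4, 1.8, 6),
            "ci_upper": np.linspace(0.6, 2.2, 6),
            "significant": False,
        })
        table = bg.forest_plot_data(eff)
        assert len(table) == 6
        assert list(table["variable"]) == [f"v{i}" for i in range(6)]
        assert (table["null_value"] == 1.0).all()

    def test_plot_data_round_trips_through_csv(self, tmp_path):
        eff = pd.DataFrame({
            "variable": ["a", "b"], "kind": "group",
            "odds_ratio": [0.9, 1.4], "ci_lower": [0.7, 1.1],
            "ci_upper": [1.2, 1.9], "significant": [False, True],
        })
        table = bg.forest_plot_data(eff)
        p = tmp_path / "forest.csv"
        table.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, table)

    def test_weight_means_sum_to_one_within_group(self, small_study):
        _, data = small_study
        model = bg.BayesianGroupIndex(data.y, data.quantiles, data.groups)
        res = model.fit(n_iter=600, n_burnin=200, seed=1)
        sums = res.weights.groupby("group")["weight"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
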