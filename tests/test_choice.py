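import numpy as np
import pandas as pd
import pytest

import chromachoice as cc
from chromachoice.choice import (
    _classify_repeatability,
    ambient_pca,
    attach_pca1,
    collinearity_screen,
    estimated_marginal_means,
    movement_rate,
    r2_mixed,
    repeatability,
    side_bias_test,
    stepwise_interaction_ladder,
    validate_choice_table,
)
from chromachoice.glmm import fit_mixed


class TestMovementRate:
    def test_values(self):
        assert movement_rate(0, 10.0) == 0.0
        assert movement_rate(12, 10.0) == pytest.approx(1.2)

    def test_random_pairs_match_division(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, d = int(rng.integers(0, 100)), float(rng.uniform(0.5, 300))
            assert movement_rate(c, d) == pytest.approx(c / d)

    def test_zero_duration_errors(self):
        with pytest.raises(ValueError):
            movement_rate(3, 0.0)


class TestSchema:
    def test_valid_table_passes(self, choice_df):
        validate_choice_table(choice_df)

    def test_missing_column_named(self, choice_df):
        with pytest.raises(ValueError, match="lux_on"):
            validate_choice_table(choice_df.drop(columns=["lux_on"]))

    def test_bad_choice_coding_rejected(self, choice_df):
        bad = choice_df.copy()
        bad.loc[bad.index[0], "choice_avoid"] = 2
        with pytest.raises(ValueError, match="choice_avoid"):
            validate_choice_table(bad)

    def test_latency_cap_enforced(self, choice_df):
        bad = choice_df.copy()
        bad.loc[bad.index[0], "latency_s"] = 601.0
        with pytest.raises(ValueError, match="600"):
            validate_choice_table(bad)


class TestCollinearity:
    def test_duplicate_column_is_perfectly_correlated(self, choice_df):
        d = choice_df.copy()
        d["lux_dup"] = d["lux_on"]
        tab = collinearity_screen(d, ["lux_on", "lux_dup"])
        assert tab["r"].iloc[0] == pytest.approx(1.0)
        assert tab["flagged"].iloc[0]

    def test_constant_variable_warns_nan(self, choice_df):
        d = choice_df.copy()
        d["const"] = 1.0
        with pytest.warns(UserWarning):
            tab = collinearity_screen(d, ["lux_on", "const"])
        assert np.isnan(tab["r"].iloc[0])

    def test_independent_pairs_rarely_flagged(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            d = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
            tab = collinearity_screen(d, ["a", "b"], threshold=0.1)
            hits += int(abs(tab["r"].iloc[0]) < 0.1)
        assert hits >= 38  # |r| < 0.1 nearly always at n=1000


class TestAmbientPCA:
    def test_first_eigenvalue_is_one_plus_r(self):
        rng = np.random.default_rng(2)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=400)
        d = pd.DataFrame(z, columns=["lux_on", "lux_off"])
        res = ambient_pca(d)
        r = np.corrcoef(z.T)[0, 1]
        assert res.eigenvalues[0] == pytest.approx(1 + abs(r), abs=1e-12)
        assert res.eigenvalues.sum() == pytest.approx(2.0, abs=1e-12)
        assert res.proportion_variance[0] == pytest.approx((1 + abs(r)) / 2, abs=1e-12)

    def test_scores_zero_mean_and_positive_loadings(self, choice_df):
        res = ambient_pca(choice_df)
        assert abs(res.scores.mean(axis=0)).max() < 1e-10
        assert np.all(res.loadings[:, 0] > 0)
        assert res.retained == [0]

    def test_uncorrelated_pair_retains_nothing(self):
        # construct an exactly orthogonal standardized pair
        n = 200
        a = np.sin(2 * np.pi * np.arange(n) / n)
        b = np.cos(2 * np.pi * np.arange(n) / n)
        d = pd.DataFrame({"lux_on": a, "lux_off": b})
        with pytest.warns(UserWarning):
            res = ambient_pca(d)
        np.testing.assert_allclose(res.eigenvalues, [1.0, 1.0], atol=1e-10)
        assert res.retained == []

    def test_constant_column_errors(self):
        d = pd.DataFrame({"lux_on": np.ones(50), "lux_off": np.arange(50.0)})
        with pytest.raises(ValueError):
            ambient_pca(d)


class TestSideBias:
    def test_balanced_outcomes_give_zero_intercept(self):
        d = pd.DataFrame(
            {"bird_id": np.repeat(np.arange(12), 4), "chose_right": np.tile([0, 1, 1, 0], 12)}
        )
        res = side_bias_test(d)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-6)
        assert res["p_value"] == pytest.approx(1.0, abs=1e-4)

    def test_all_one_side_raises_separation(self):
        d = pd.DataFrame({"bird_id": np.repeat(np.arange(6), 3), "chose_right": 1})
        with pytest.raises(ValueError, match="separation"):
            side_bias_test(d)

    def test_biased_data_detected(self):
        df = cc.synth_side_bias_dataset(n_birds=60, trials_per_bird=20, p_right=0.25,
                                        sigma_b=0.2, seed=5)
        res = side_bias_test(df)
        assert res["intercept"] < 0
        assert res["p_value"] < 0.001


class TestLadder:
    def test_reports_all_five_interactions(self, choice_df):
        fit, rep = stepwise_interaction_ladder(choice_df, "choice_avoid", family="binomial")
        tested = {s["term"] for s in rep.steps}
        assert tested == {
            "color:frequency", "color:trial_order", "frequency:trial_order",
            "color:pca1", "frequency:pca1",
        }
        assert rep.final_formula.startswith("choice_avoid ~")

    def test_detects_builtin_color_order_interaction(self):
        p = cc.ChoiceSimParams(n_birds=40, seed=42, color_order_reversal=1.5,
                               beta_table={}, freq_ambient_coef=0.0, mistrial_prob=0.0)
        df = attach_pca1(cc.synth_choice_dataset(p))
        fit, rep = stepwise_interaction_ladder(df, "choice_avoid", family="binomial")
        assert "color:trial_order" in rep.kept_interactions

    def test_gaussian_ladder_runs_with_f_tests(self, choice_df):
        fit, rep = stepwise_interaction_ladder(choice_df, "latency_s", family="gaussian")
        step1 = rep.steps[0]
        assert step1["term"] == "color:frequency"
        assert isinstance(step1["df"], tuple)  # (num df, Satterthwaite denom df)


class TestEmmeans:
    def test_balanced_one_factor_equals_group_means(self):
        rng = np.random.default_rng(4)
        G = 10
        rows = []
        for g in range(G):
            for color in ("blue", "red"):
                for _ in range(2):
                    rows.append({"bird_id": g, "color": color,
                                 "y": {"blue": 5.0, "red": 8.0}[color] + rng.normal(0, 0.5)})
        d = pd.DataFrame(rows)
        fit = fit_mixed(d, "y ~ C(color, Sum)", family="gaussian")
        emm = estimated_marginal_means(fit, "color").set_index("level")
        obs = d.groupby("color")["y"].mean()
        assert emm.loc["blue", "mean"] == pytest.approx(obs["blue"], abs=1e-8)
        assert emm.loc["red", "mean"] == pytest.approx(obs["red"], abs=1e-8)

    def test_matches_manual_grid_enumeration(self, choice_df):
        fit = fit_mixed(
            choice_df,
            "latency_s ~ C(color, Sum) + C(frequency, Sum) + C(trial_order, Sum) + pca1",
            family="gaussian",
        )
        emm = estimated_marginal_means(fit, "color").set_index("level")
        # independent enumeration: predict every grid cell, average per color
        import patsy

        cells = []
        for color in ("blue", "red"):
            for freq in ("pulsing", "steady"):
                for order in sorted(choice_df["trial_order"].unique()):
                    cells.append({"color": color, "frequency": freq,
                                  "trial_order": order, "pca1": choice_df["pca1"].mean()})
        gridf = pd.DataFrame(cells)
        (Xg,) = patsy.build_design_matrices([fit.design_info], gridf)
        preds = np.asarray(Xg) @ fit.params
        manual = pd.Series(preds).groupby(gridf["color"]).mean()
        assert emm.loc["blue", "mean"] == pytest.approx(manual["blue"], rel=1e-10)
        assert emm.loc["red", "mean"] == pytest.approx(manual["red"], rel=1e-10)

    def test_binomial_means_on_probability_scale(self, choice_df):
        fit = fit_mixed(
            choice_df,
            "choice_avoid ~ C(color, Sum) + C(frequency, Sum) + C(trial_order, Sum) + pca1",
            family="binomial",
        )
        emm = estimated_marginal_means(fit, "color")
        assert ((emm["mean"] > 0) & (emm["mean"] < 1)).all()

    def test_absent_factor_errors(self, choice_df):
        fit = fit_mixed(choice_df, "latency_s ~ C(color, Sum)", family="gaussian")
        with pytest.raises(ValueError):
            estimated_marginal_means(fit, "nonexistent")


class TestR2AndRepeatability:
    def test_zero_random_variance_makes_r2_equal(self):
        rng = np.random.default_rng(5)
        d = pd.DataFrame(
            {"bird_id": np.repeat(np.arange(20), 5),
             "x": rng.normal(size=100)}
        )
        d["y"] = 2 * d["x"] + rng.normal(0, 1, 100)  # no bird effect
        fit = fit_mixed(d, "y ~ x", family="gaussian")
        marg, cond = r2_mixed(fit)
        assert fit.var_individual == pytest.approx(0.0, abs=1e-4)
        assert marg == pytest.approx(cond, abs=0.1)

    def test_known_variance_decomposition_recovered(self):
        # Vf = Vi = Vr = 1, so marginal -> 33.3% and conditional -> 66.7%;
        # averaged over replicates to beat Monte-Carlo noise in the V components
        rng = np.random.default_rng(6)
        margs, conds = [], []
        for _ in range(20):
            G, n = 60, 8
            x = rng.normal(size=G * n)
            b = rng.normal(0, 1.0, G)
            y = 1.0 * x + np.repeat(b, n) + rng.normal(0, 1.0, G * n)
            d = pd.DataFrame({"bird_id": np.repeat(np.arange(G), n), "x": x, "y": y})
            marg, cond = r2_mixed(fit_mixed(d, "y ~ x", family="gaussian"))
            margs.append(marg)
            conds.append(cond)
        assert np.mean(margs) == pytest.approx(100 / 3, abs=3.0)
        assert np.mean(conds) == pytest.approx(200 / 3, abs=3.0)

    def test_category_boundaries(self):
        assert _classify_repeatability(20.0) == "low"
        assert _classify_repeatability(40.0) == "moderate"
        assert _classify_repeatability(41.0) == "high"

    def test_zero_individual_variance_is_low(self):
        rng = np.random.default_rng(7)
        d = pd.DataFrame({"bird_id": np.repeat(np.arange(20), 5),
                          "y": rng.normal(size=100)})
        fit = fit_mixed(d, "y ~ 1", family="gaussian")
        rep = repeatability(fit, n_boot=0)
        assert rep.value == pytest.approx(0.0, abs=1.0)
        assert rep.category == "low"

    def test_invariant_to_response_rescaling(self):
        rng = np.random.default_rng(8)
        G, n = 30, 8
        b = rng.normal(0, 2, G)
        y = np.repeat(b, n) + rng.normal(0, 3, G * n)
        d = pd.DataFrame({"bird_id": np.repeat(np.arange(G), n), "y": y})
        f1 = fit_mixed(d, "y ~ 1", family="gaussian")
        d10 = d.assign(y=10 * d["y"])
        f2 = fit_mixed(d10, "y ~ 1", family="gaussian")
        r1, r2 = repeatability(f1, n_boot=0), repeatability(f2, n_boot=0)
        assert r1.value == pytest.approx(r2.value, abs=1e-4)

    def test_bootstrap_ci_brackets_estimate(self, choice_df):
        fit = fit_mixed(choice_df, "latency_s ~ C(color, Sum)", family="gaussian")
        rep = repeatability(fit, n_boot=60, seed=1)
        assert rep.ci_low <= rep.value <= rep.ci_high
        assert 0.0 <= rep.ci_low and rep.ci_high <= 100.0
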