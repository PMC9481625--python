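"""Feature expansion, the MaxEnt fit, prediction scales and AICc."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from alleleniche.maxent import (FeatureExpansion, MaxentNicheModel,
                                auto_feature_classes, build_features,
                                fit_maxent, tune_model)


def toy_values(x, name="v"):
    return pd.DataFrame({name: np.asarray(x, float)})


class TestFeatureExpansion:
    def test_linear_minmax_scaling(self):
        F, exp = build_features(toy_values([0.0, 5.0, 10.0]), "L")
        np.testing.assert_allclose(F[:, 0], [0.0, 0.5, 1.0])

    def test_forward_hinge_closed_form(self):
        exp = FeatureExpansion.from_training(toy_values([0.0, 1.0]), "H",
                                             n_hinge_knots=3)
        # interior knots at 0.25/0.5/0.75; forward hinge with knot 0.5
        # evaluated at scaled 0.75 -> (0.75 - 0.5) / (1 - 0.5) = 0.5
        F = exp.transform(toy_values([0.75]))
        i = exp.feature_names.index("hingeF:v@0.5000")
        assert F[0, i] == pytest.approx(0.5)

    def test_column_counts(self):
        vals = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [1.0, 0.0, 3.0]})
        F, exp = build_features(vals, "LQP")
        assert F.shape[1] == 2 + 2 + 1
        F, exp = build_features(vals, "LQH", n_hinge_knots=8)
        assert F.shape[1] == 2 + 2 + 2 * 2 * 8

    def test_all_columns_bounded_on_training_data(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        F, _ = build_features(vals, "LQPH")
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_zero_variance_variable_named(self):
        vals = pd.DataFrame({"ok": [0.0, 1.0], "flat": [2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            build_features(vals, "L")

    def test_clamping_truncates(self):
        exp = FeatureExpansion.from_training(toy_values([0.0, 1.0]), "L")
        assert exp.transform(toy_values([2.0]), clamp=True)[0, 0] == 1.0
        assert exp.transform(toy_values([2.0]), clamp=False)[0, 0] == 2.0

    def test_auto_classes_by_presence_count(self):
        assert auto_feature_classes(9) == {"linear"}
        assert auto_feature_classes(12) == {"linear", "quadratic"}
        assert auto_feature_classes(40) == {"linear", "quadratic", "hinge"}
        assert "product" in auto_feature_classes(80)


def simple_problem(seed=0, n_pres=30, n_bg=500):
    rng = np.random.default_rng(seed)
    bg = pd.DataFrame({"v": rng.uniform(0, 1, n_bg)})
    pres = pd.DataFrame({"v": rng.beta(5, 2, n_pres)})
    return pres, bg


class TestFit:
    def test_infinite_regularization_gives_uniform(self):
        pres, bg = simple_problem()
        res = fit_maxent(pres, bg, feature_classes="LQ",
                         reg_multiplier=np.inf)
        assert np.all(res.params == 0.0)
        assert res.entropy == pytest.approx(np.log(len(bg)))
        surf = res.predict(bg, output_scale="raw")
        np.testing.assert_allclose(surf, 1.0 / len(bg))

    def test_single_binary_feature_matches_grid_oracle(self):
        # presences all 1, half of background 1, tiny beta: the 1-D convex
        # problem is solved independently by dense grid search
        pres = pd.DataFrame({"v": np.ones(20)})
        pres.iloc[0] = 0.0  # avoid a degenerate (constant) presence set
        bg = pd.DataFrame({"v": np.repeat([0.0, 1.0], 100)})
        model = MaxentNicheModel(pres, bg, feature_classes="L",
                                 reg_multiplier=1e-6)
        res = model.fit(tol=1e-10, max_iter=2000)
        lam_grid = np.linspace(-1, 8, 40_001)
        Fb = model.F_background[:, 0]
        emp = model.F_presence[:, 0].mean()
        obj = [-emp * l + logsumexp(Fb * l) + model._beta[0] * abs(l)
               for l in lam_grid]
        best = lam_grid[int(np.argmin(obj))]
        assert model.objective(res.params.to_numpy()) <= min(obj) + 1e-3
        assert res.params.iloc[0] == pytest.approx(best, abs=0.01)
        # fitted model mean of the feature ~ empirical mean
        assert res.model_means().iloc[0] == pytest.approx(emp, abs=1e-3)

    def test_objective_path_non_increasing(self):
        pres, bg = simple_problem(1)
        model = MaxentNicheModel(pres, bg, feature_classes="LQH")
        res = model.fit()
        path = np.array(res.objective_path)
        assert np.all(np.diff(path) <= 1e-10)

    def test_kkt_stationarity(self):
        pres, bg = simple_problem(2)
        model = MaxentNicheModel(pres, bg, feature_classes="LQ")
        res = model.fit(tol=1e-9, max_iter=2000)
        gaps = res.kkt_gaps().to_numpy()
        beta = res.beta.to_numpy()
        assert np.all(gaps <= beta + 1e-6)

    def test_convexity_oracle_three_features(self):
        """Fitted objective matches a dense grid search on a 2-feature problem."""
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"v": rng.uniform(0, 1, 300)})
        pres = pd.DataFrame({"v": rng.beta(2, 4, 25)})
        model = MaxentNicheModel(pres, bg, feature_classes="LQ",
                                 reg_multiplier=1.0)
        res = model.fit(tol=1e-10, max_iter=2000)
        grid = np.linspace(-6, 6, 241)
        best = min(model.objective(np.array([l1, l2]))
                   for l1 in grid for l2 in grid)
        fitted = model.objective(res.params.to_numpy())
        assert fitted <= best + 1e-3

    def test_degenerate_presences_error(self):
        pres = pd.DataFrame({"v": np.full(5, 0.5)})
        bg = pd.DataFrame({"v": np.linspace(0, 1, 50)})
        with pytest.raises(ValueError, match="degenerate"):
            MaxentNicheModel(pres, bg, feature_classes="L")

    def test_background_must_exceed_presences(self):
        pres, _ = simple_problem(0, n_pres=30)
        with pytest.raises(ValueError, match="background"):
            MaxentNicheModel(pres, pres, feature_classes="L")

    def test_summary_mentions_fit_facts(self):
        pres, bg = simple_problem(3)
        res = fit_maxent(pres, bg, feature_classes="L")
        text = res.summary()
        assert "presences: 30" in text and "entropy" in text


class TestPrediction:
    def test_raw_sums_to_one(self, small_world):
        from alleleniche.geo import extract_values, sample_background
        stack = small_world.present
        pres = extract_values(stack, small_world.occurrences.for_allele("HbS"))
        bg, _ = sample_background(stack, 500, 0)
        res = fit_maxent(pres, bg, feature_classes="LQ")
        surf = res.predict_surface(stack, output_scale="raw")
        assert surf.mask_values().sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_model_cloglog_constant(self, small_world):
        from alleleniche.geo import extract_values, sample_background
        stack = small_world.present
        pres = extract_values(stack, small_world.occurrences.for_allele("HbS"))
        bg, _ = sample_background(stack, 500, 0)
        res = fit_maxent(pres, bg, feature_classes="L", reg_multiplier=np.inf)
        surf = res.predict_surface(stack, output_scale="cloglog")
        np.testing.assert_allclose(surf.mask_values(), 1.0 - np.exp(-1.0),
                                   atol=1e-12)

    def test_cumulative_extremes(self, small_world):
        from alleleniche.geo import extract_values, sample_background
        stack = small_world.present
        pres = extract_values(stack, small_world.occurrences.for_allele("HbF"))
        bg, _ = sample_background(stack, 500, 0)
        res = fit_maxent(pres, bg, feature_classes="LQ")
        raw = res.predict_surface(stack, output_scale="raw").mask_values()
        cum = res.predict_surface(stack, output_scale="cumulative").mask_values()
        assert cum[np.argmax(raw)] == pytest.approx(1.0, abs=1e-12)
        assert cum[np.argmin(raw)] == pytest.approx(raw.min() if
                                                    (raw == raw.min()).sum() == 1
                                                    else cum[np.argmin(raw)])
        assert np.all((cum > 0) & (cum <= 1))

    def test_clamp_irrelevant_on_training_stack(self, small_world):
        from alleleniche.geo import extract_values, sample_background
        stack = small_world.present
        pres = extract_values(stack, small_world.occurrences.for_allele("HbS"))
        bg, _ = sample_background(stack, 500, 0)
        res = fit_maxent(pres, bg, feature_classes="LQ")
        # training range is the pooled presence+background range, which may
        # not cover the whole stack; restrict the check to in-range cells
        a = res.predict_surface(stack, output_scale="raw", clamp=True)
        b = res.predict_surface(stack, output_scale="raw", clamp=False)
        in_range = ~res.clamping_mask(stack)
        m = a.mask & in_range
        # identical up to renormalization over the shared domain
        ratio = a.values[m] / b.values[m]
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_missing_variable_errors(self, small_world):
        from alleleniche.geo import extract_values, sample_background
        stack = small_world.present
        pres = extract_values(stack, small_world.occurrences.for_allele("HbS"))
        bg, _ = sample_background(stack, 500, 0)
        res = fit_maxent(pres, bg, feature_classes="L")
        with pytest.raises(KeyError, match="BIO13"):
            res.predict_surface(stack.subset(["BIO10"]))


class TestAicc:
    def test_uniform_model_closed_form(self):
        # K=0 uniform model, 10 presences, 100-cell landscape:
        # lnL = 10 ln(0.01), AICc = -2 lnL = 92.103
        rng = np.random.default_rng(0)
        bg = pd.DataFrame({"v": rng.uniform(0, 1, 100)})
        pres = pd.DataFrame({"v": rng.uniform(0, 1, 10)})
        res = fit_maxent(pres, bg, feature_classes="L", reg_multiplier=np.inf)
        assert res.n_active == 0
        aicc = res.aicc(presence_values=pres, landscape=bg)
        assert aicc == pytest.approx(-2 * 10 * np.log(0.01), abs=1e-9)
        assert aicc == pytest.approx(92.103, abs=1e-3)

    def test_invalid_when_k_reaches_n(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({f"v{i}": rng.uniform(0, 1, 200) for i in range(4)})
        pres = pd.DataFrame({f"v{i}": rng.beta(4, 2, 5) for i in range(4)})
        res = fit_maxent(pres, bg, feature_classes="LQ", reg_multiplier=0.01)
        if res.n_active >= len(pres) - 1:
            assert np.isnan(res.aicc())

    def test_zero_coefficient_features_do_not_count(self):
        pres, bg = simple_problem(4)
        res_small = fit_maxent(pres, bg, feature_classes="L")
        # heavy regularization drives extra features to exactly zero
        res_big = fit_maxent(pres, bg, feature_classes="LQH",
                             reg_multiplier=50.0)
        assert res_big.n_active <= res_small.model.expansion.n_features + 1


class TestTuning:
    def test_single_candidate_wins(self):
        pres, bg = simple_problem(6)
        result = tune_model(pres, bg, candidate_feature_sets=["L"],
                            candidate_multipliers=[1.0])
        assert result.best_classes == "L"
        assert result.best_multiplier == 1.0
        assert len(result.table) == 1

    def test_invalid_candidate_excluded(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({f"v{i}": rng.uniform(0, 1, 300) for i in range(2)})
        pres = pd.DataFrame({f"v{i}": rng.beta(5, 2, 4) for i in range(2)})
        # n=4 presences: a candidate with K >= 3 active features is invalid
        result = tune_model(pres, bg, candidate_feature_sets=["L", "LQP"],
                            candidate_multipliers=[0.01])
        invalid = result.table[~result.table["valid"]]
        assert result.best_classes not in set(invalid["feature_classes"])

    def test_gaussian_niche_prefers_quadratic(self, small_world):
        """On a product-Gaussian truth the AICc winner includes quadratic terms."""
        from alleleniche.geo import extract_values, sample_background
        stack = small_world.present
        pres = extract_values(stack, small_world.occurrences.for_allele("HbS"))
        bg, _ = sample_background(stack, 800, 0)
        result = tune_model(pres, bg, candidate_feature_sets=["L", "LQ"],
                            candidate_multipliers=[0.5, 1.0, 2.0])
        assert "Q" in result.best_classes
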