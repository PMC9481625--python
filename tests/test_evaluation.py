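"""AUC, partial ROC, replicate splitting and variable selection."""

import numpy as np
import pandas as pd
import pytest

from alleleniche import synthetic
from alleleniche.evaluation import (auc, jackknife_importance, partial_auc_ratio,
                                    select_variables, subsample_replicates)
from alleleniche.geo import extract_values, sample_background
from alleleniche.maxent import ModelSettings, fit_maxent


class TestAuc:
    @pytest.mark.parametrize("pres,bg,expected", [
        ([0.9, 0.8], [0.1, 0.2], 1.0),          # perfect separation
        ([0.5, 0.5], [0.5, 0.5], 0.5),          # all ties
        ([0.7, 0.3], [0.5], 0.5),               # one win, one loss of 2 pairs
    ])
    def test_enumerable_cases(self, pres, bg, expected):
        assert auc(pres, bg) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.5])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        p, b = rng.normal(1, 1, 50), rng.normal(0, 1, 200)
        base = auc(p, b)
        for f in (np.exp, np.tanh, lambda x: x ** 3):
            assert auc(f(p), f(b)) == pytest.approx(base)

    def test_agrees_with_mannwhitney(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(1)
        p, b = rng.normal(0.5, 1, 40), rng.normal(0, 1, 100)
        u = mannwhitneyu(p, b, alternative="two-sided").statistic
        assert auc(p, b) == pytest.approx(u / (len(p) * len(b)))


class TestPartialAuc:
    def test_perfect_separation(self):
        p = np.linspace(0.8, 1.0, 30)
        b = np.linspace(0.0, 0.5, 200)
        ratio, pval = partial_auc_ratio(p, b, seed=0)
        assert ratio > 1.9  # near the maximum of 2 for E = 0.05
        assert pval == 0.0

    def test_null_calibration(self):
        # presence scores drawn from the background distribution: ratio ~ 1
        rng = np.random.default_rng(42)
        scores = rng.uniform(0, 1, 400)
        ratio, _ = partial_auc_ratio(scores[:200], scores[200:],
                                     n_boot=100, seed=1)
        assert 0.9 <= ratio <= 1.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        p, b = rng.normal(1, 1, 50), rng.normal(0, 1, 100)
        assert partial_auc_ratio(p, b, seed=7) == partial_auc_ratio(p, b, seed=7)

    def test_too_few_presences_errors(self):
        with pytest.raises(ValueError, match="resample"):
            partial_auc_ratio([0.5], [0.1, 0.2], resample_fraction=0.3)

    def test_omission_bounds(self):
        with pytest.raises(ValueError):
            partial_auc_ratio([0.5, 0.6], [0.1], omission_E=0.7)


class TestSubsampleReplicates:
    def test_split_sizes(self):
        reps = subsample_replicates(10, 5, 0.3, seed=0)
        for train, test in reps:
            assert len(test) == 3 and len(train) == 7

    def test_partition_is_exact(self):
        reps = subsample_replicates(10, 5, 0.3, seed=1)
        for train, test in reps:
            assert sorted(np.concatenate([train, test])) == list(range(10))
            assert not set(train) & set(test)

    def test_deterministic(self):
        a = subsample_replicates(20, 50, 0.25, seed=5)
        b = subsample_replicates(20, 50, 0.25, seed=5)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_impossible_sizes_error(self):
        with pytest.raises(ValueError):
            subsample_replicates(3, 5, 0.01, seed=0)


@pytest.fixture(scope="module")
def informative_and_noise():
    """2 informative + 4 noise variables; HbS-like presences on the first two."""
    world = synthetic.make_world(
        seed=13, n_rows=50, n_cols=50,
        var_names=["BIO10", "BIO13", "N1", "N2", "N3", "N4"],
        smoothing_scale=3.0, inter_var_correlation=0.0,
        niches={"A": synthetic.NicheTruth("A", {"BIO10": -1.0, "BIO13": 0.8},
                                          {"BIO10": 0.8, "BIO13": 1.0})},
        n_per_allele={"A": 40}, min_distance_km=0.0)
    pres = extract_values(world.present, world.occurrences)
    bg, _ = sample_background(world.present, 1500, 0)
    return world, pres, bg


class TestJackknife:
    def test_noise_variable_has_no_gain(self, informative_and_noise):
        _, pres, bg = informative_and_noise
        table = jackknife_importance(pres, bg, settings=ModelSettings("LQ"))
        assert table.loc["N1", "gain_alone"] <= 0.05
        assert table.loc["BIO10", "gain_alone"] > 0.2

    def test_full_model_nests_drop_one(self, informative_and_noise):
        """The full fit's regularized objective is never worse than any
        drop-one fit's (exact nesting); the unregularized gain is nested up
        to the L1 penalty the extra features pay."""
        _, pres, bg = informative_and_noise
        settings = ModelSettings("LQ", tol=1e-8, max_iter=2000)
        table = jackknife_importance(pres, bg, settings=settings)
        full_fit = settings.fit(pres, bg)
        full_obj = full_fit.model.objective(full_fit.params.to_numpy())
        for v in pres.columns:
            others = [w for w in pres.columns if w != v]
            sub = settings.fit(pres[others], bg[others])
            sub_obj = sub.model.objective(sub.params.to_numpy())
            # the drop-one optimum embeds into the full problem with the
            # missing feature at zero and identical penalties
            assert full_obj <= sub_obj + 1e-6
        penalty_slack = float(
            (full_fit.beta * full_fit.params.abs()).sum()) + 1e-6
        assert (full_fit.training_gain
                >= table["gain_without"] - penalty_slack).all()

    def test_duplicate_variable_is_redundant(self, informative_and_noise):
        _, pres, bg = informative_and_noise
        p = pres[["BIO10", "BIO13"]].copy()
        b = bg[["BIO10", "BIO13"]].copy()
        p["BIO10_copy"] = p["BIO10"]
        b["BIO10_copy"] = b["BIO10"]
        settings = ModelSettings("LQ")
        full = settings.fit(p, b).training_gain
        table = jackknife_importance(p, b, settings=settings)
        assert abs(full - table.loc["BIO10_copy", "gain_without"]) <= 1e-3


class TestSelectVariables:
    def test_informative_variables_survive(self, informative_and_noise):
        world, _, _ = informative_and_noise
        report = select_variables(world.present, world.occurrences,
                                  r_threshold=0.8, target_k=4,
                                  settings=ModelSettings("LQ"), seed=0)
        assert {"BIO10", "BIO13"} <= set(report.final_variables)
        assert len(report.final_variables) <= 4

    def test_perfectly_correlated_copy_removed(self, informative_and_noise):
        world, _, _ = informative_and_noise
        import numpy as np
        from alleleniche.geo import ClimateStack
        data = np.concatenate([world.present.data[:2],
                               world.present.data[:1]])  # BIO10 duplicated
        stack = ClimateStack(["BIO10", "BIO13", "BIO10_copy"], data.copy(),
                             world.present.xllcorner, world.present.yllcorner,
                             world.present.cellsize)
        report = select_variables(stack, world.occurrences, r_threshold=0.8,
                                  target_k=3, settings=ModelSettings("LQ"),
                                  seed=0)
        survivors = set(report.final_variables)
        assert len(survivors & {"BIO10", "BIO10_copy"}) == 1
        corr = report.correlation_matrix
        final_corr = corr.loc[report.final_variables, report.final_variables]
        off = final_corr.to_numpy()[~np.eye(len(final_corr), dtype=bool)]
        assert np.all(np.abs(off) <= 0.8)

    def test_r_threshold_one_removes_nothing(self, informative_and_noise):
        world, _, _ = informative_and_noise
        report = select_variables(world.present, world.occurrences,
                                  r_threshold=1.0, target_k=4,
                                  settings=ModelSettings("LQ"), seed=0)
        assert len(report.final_variables) == 4

    def test_too_few_variables_error(self, informative_and_noise):
        world, _, _ = informative_and_noise
        with pytest.raises(ValueError):
            select_variables(world.present, world.occurrences, target_k=10)


def test_noise_only_models_are_chance_level():
    """Mean AUC of models fit to uniformly sampled presences is ~0.5."""
    world = synthetic.make_world(
        seed=99, n_rows=40, n_cols=40, var_names=["A", "B"],
        smoothing_scale=3.0, inter_var_correlation=0.0,
        niches={"X": synthetic.NicheTruth("X", {"A": 0.0}, {"A": 1e6})},
        n_per_allele={"X": 40}, min_distance_km=0.0)
    pres = extract_values(world.present, world.occurrences)
    bg, _ = sample_background(world.present, 800, 0)
    reps = subsample_replicates(len(pres), 20, 0.25, seed=0)
    aucs = []
    for train, test in reps:
        res = fit_maxent(pres.iloc[train], bg, feature_classes="LQ")
        aucs.append(auc(res.predict(pres.iloc[test]), res.predict(bg)))
    assert 0.4 <= np.mean(aucs) <= 0.6
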