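"""Grid-searched model training, PS semantics and y-randomization."""

import numpy as np
import pytest

from toxscope import (Family, FixtureSpec, ModelConfig, classify_ps,
                      default_grid, generate_dataset, grid_search_cv,
                      predict_ps, random_split, train_final, y_randomization)


@pytest.fixture(scope="module")
def small_split():
    records = generate_dataset(FixtureSpec(n_compounds=80, seed=4,
                                           class_balance=0.6))
    return random_split(records, 0.8, seed=4)


TINY_RF = {"max_features": ["sqrt"], "n_estimators": [20]}


class TestDefaultGrids:
    def test_default_grid_shapes(self):
        rf = default_grid("RF")
        assert rf["max_features"] == ["sqrt", "log2", None]
        assert rf["n_estimators"] == [100, 500]
        knn = default_grid("KNN")
        assert knn["n_neighbors"] == list(range(1, 16))
        mlp = default_grid("MLP")
        assert len(mlp["hidden_layer_sizes"]) == 3 + 9 + 27
        assert set(mlp["solver"]) == {"lbfgs", "adam", "sgd"}
        assert set(mlp["activation"]) == {"identity", "logistic", "tanh", "relu"}
        assert mlp["learning_rate_init"] == [0.01, 0.001, 0.0001]

    def test_invalid_grid_keys_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(algorithm="RF", family=Family.MORGAN,
                        grid={"bogus": [1]})


class TestGridSearch:
    def test_single_point_grid_is_selected(self, small_split):
        config = ModelConfig("RF", Family.MORGAN, grid=TINY_RF, seed=0,
                             n_folds=3)
        cv = grid_search_cv(small_split.train, config)
        assert cv.best_params == {"max_features": "sqrt", "n_estimators": 20}

    def test_twenty_folds_give_twenty_mcc_values(self, small_split):
        config = ModelConfig("RF", Family.MORGAN, grid=TINY_RF, seed=0,
                             n_folds=20)
        cv = grid_search_cv(small_split.train, config)
        assert len(cv.fold_mcc) == 20
        assert all(-1.0 <= m <= 1.0 for m in cv.fold_mcc)

    def test_selection_maximizes_mean_cv_mcc(self, small_split):
        config = ModelConfig("KNN", Family.MORGAN,
                             grid={"n_neighbors": [1, 3],
                                   "weights": ["uniform"]},
                             seed=0, n_folds=5)
        cv = grid_search_cv(small_split.train, config)
        best_mean = max(row["mean_mcc"] for row in cv.grid_table)
        assert cv.mean_mcc == pytest.approx(best_mean)

    def test_single_class_training_rejected(self, small_split):
        toxic_only = [r for r in small_split.train if r.label == 1]
        config = ModelConfig("RF", Family.MORGAN, grid=TINY_RF)
        with pytest.raises(ValueError):
            grid_search_cv(toxic_only, config)


class TestPredictPS:
    def test_ps_in_unit_interval_and_threshold(self, small_split):
        config = ModelConfig("RF", Family.MORGAN, grid=TINY_RF, seed=1,
                             n_folds=3)
        model = train_final(small_split.train, config,
                            {"max_features": "sqrt", "n_estimators": 20})
        ps = predict_ps(model, [r.mol for r in small_split.test])
        assert ps.min() >= 0.0 and ps.max() <= 1.0

    def test_threshold_is_inclusive_at_half(self):
        assert classify_ps(0.5) == 1
        assert classify_ps(0.49) == 0
        assert classify_ps(np.array([0.5, 0.49, 1.0])).tolist() == [1, 0, 1]

    def test_same_seed_identical_predictions(self, small_split):
        mols = [r.mol for r in small_split.test]
        configs = [ModelConfig("RF", Family.MORGAN, grid=TINY_RF, seed=7)
                   for _ in range(2)]
        ps = [predict_ps(train_final(small_split.train, c,
                                     {"max_features": "sqrt",
                                      "n_estimators": 20}), mols)
              for c in configs]
        assert np.array_equal(ps[0], ps[1])

    @pytest.mark.parametrize("algorithm,family,hp", [
        ("RF", Family.MORGAN, {"max_features": "sqrt", "n_estimators": 100}),
        ("KNN", Family.PUBCHEM, {"n_neighbors": 1}),
    ])
    def test_separable_data_reaches_perfect_test_mcc(self, small_split,
                                                     algorithm, family, hp):
        # noise-free planted labels are recoverable exactly: the substructure
        # key encodes the nitroaromatic group as explicit bits
        from toxscope import evaluate
        config = ModelConfig(algorithm, family,
                             grid={k: [v] for k, v in hp.items()},
                             seed=0, n_folds=3)
        model = train_final(small_split.train, config, hp)
        ps = predict_ps(model, [r.mol for r in small_split.test])
        y = [r.label for r in small_split.test]
        assert evaluate(y, classify_ps(ps)).mcc == 1.0


class TestYRandomization:
    def test_shuffles_are_reproducible(self, small_split):
        config = ModelConfig("RF", Family.MORGAN, grid=TINY_RF, seed=0)
        kwargs = dict(config=config,
                      hyperparams={"max_features": "sqrt", "n_estimators": 20},
                      n_rounds=3, seed=5)
        a = y_randomization(small_split.train, small_split.test, **kwargs)
        b = y_randomization(small_split.train, small_split.test, **kwargs)
        assert [r.mcc for r in a] == [r.mcc for r in b]
        assert len(a) == 3

    def test_rejects_zero_rounds(self, small_split):
        config = ModelConfig("RF", Family.MORGAN, grid=TINY_RF)
        with pytest.raises(ValueError):
            y_randomization(small_split.train, small_split.test, config,
                            {"n_estimators": 20}, n_rounds=0)
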