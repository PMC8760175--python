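import numpy as np
import pytest

from aievote.dataio import ACQ, AIE
from aievote.models import (
    FAMILIES,
    ClassifierSpec,
    build_grid,
    make_estimator,
    predict_labels,
    predict_scores,
    tune_classifier,
)


@pytest.fixture(scope="module")
def separable():
    """40 points in 2-D, linearly separable with a wide margin."""
    rng = np.random.default_rng(3)
    pos = rng.normal(loc=(3.0, 3.0), scale=0.3, size=(20, 2))
    neg = rng.normal(loc=(-3.0, -3.0), scale=0.3, size=(20, 2))
    X = np.vstack([pos, neg])
    y = np.array([AIE] * 20 + [ACQ] * 20)
    return X, y


class TestGrids:
    def test_knn_grid_is_the_printed_nine_values(self):
        assert build_grid("knn").grid["n_neighbors"] == [3, 5, 7, 9, 11, 13, 15, 17, 18]

    def test_random_forest_grid_has_ten_points(self):
        spec = build_grid("random_forest")
        assert len(spec.candidates()) == 10
        assert spec.grid["n_estimators"] == [10, 50, 100, 200, 500]

    def test_logistic_grid_is_log_spaced_over_printed_range(self):
        values = build_grid("logistic_regression").grid["C"]
        # oracle: 7 log-spaced points between the printed endpoints
        np.testing.assert_allclose(values, np.logspace(-3, 3, 7))

    def test_mlp_grid_within_printed_ranges(self):
        grid = build_grid("mlp").grid
        assert min(grid["learning_rate_init"]) == pytest.approx(1e-5)
        assert max(grid["learning_rate_init"]) == pytest.approx(1e-1)
        assert grid["alpha"] == [1e-5, 1e-4, 1e-3]

    def test_gradient_boost_ranges(self):
        grid = build_grid("gradient_boost").grid
        assert min(grid["min_samples_split"]) >= 0.1
        assert max(grid["min_samples_split"]) <= 0.5
        assert grid["max_depth"] == [3, 5, 7]
        assert grid["subsample"] == [0.5, 0.75, 0.95]

    def test_reduced_preset_has_at_most_two_points_per_hyperparameter(self):
        for family in FAMILIES:
            for values in build_grid(family, "reduced").grid.values():
                assert 1 <= len(values) <= 2

    def test_unknown_family_or_preset_errors(self):
        with pytest.raises(ValueError):
            build_grid("svm")
        with pytest.raises(ValueError):
            build_grid("knn", preset="huge")

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("knn", {"n_neighbors": []})


class TestTuning:
    def test_single_candidate_is_chosen_and_scored(self, separable):
        X, y = separable
        spec = ClassifierSpec("knn", {"n_neighbors": [3]})
        tuned = tune_classifier(spec, X, y, inner_folds=5, seed=0)
        assert tuned.chosen_params == {"n_neighbors": 3}
        assert 0.0 <= tuned.inner_cv_score <= 1.0

    def test_better_generalizing_candidate_wins(self):
        # overlapping clusters with a few mislabeled points: 1-NN memorizes
        # the noise while k=11 smooths over it and scores higher in inner CV
        rng = np.random.default_rng(3)
        X = np.vstack([
            rng.normal(loc=(1.0, 1.0), scale=1.0, size=(20, 2)),
            rng.normal(loc=(-1.0, -1.0), scale=1.0, size=(20, 2)),
        ])
        y = np.array([AIE] * 20 + [ACQ] * 20)
        y[[0, 1, 20, 21]] = [ACQ, ACQ, AIE, AIE]
        spec = ClassifierSpec("knn", {"n_neighbors": [1, 11]})
        tuned = tune_classifier(spec, X, y.tolist(), inner_folds=5, seed=0)
        assert tuned.chosen_params == {"n_neighbors": 11}

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_solves_a_separable_toy_set(self, family, separable):
        X, y = separable
        tuned = tune_classifier(build_grid(family, "reduced"), X, y, inner_folds=5, seed=1)
        assert tuned.inner_cv_score == 1.0
        assert (predict_labels(tuned, X) == y).all()

    def test_chosen_params_always_come_from_the_grid(self, separable):
        X, y = separable
        for family in FAMILIES:
            spec = build_grid(family, "reduced")
            tuned = tune_classifier(spec, X, y, seed=2)
            for key, value in tuned.chosen_params.items():
                assert value in spec.grid[key]

    def test_fixed_seed_reproduces_selection(self, separable, rng):
        X, y = separable
        X = X + rng.normal(scale=2.0, size=X.shape)  # make folds matter
        spec = build_grid("random_forest", "reduced")
        a = tune_classifier(spec, X, y, seed=7)
        b = tune_classifier(spec, X, y, seed=7)
        assert a.chosen_params == b.chosen_params
        assert a.inner_cv_score == b.inner_cv_score

    def test_deterministic_families_are_seed_invariant_in_fit(self, separable):
        X, y = separable
        for family in ("logistic_regression", "knn"):
            spec = ClassifierSpec(family, {k: v[:1] for k, v in build_grid(family).grid.items()})
            a = tune_classifier(spec, X, y, seed=1)
            b = tune_classifier(spec, X, y, seed=2)  # different fold shuffles
            np.testing.assert_array_equal(predict_scores(a, X), predict_scores(b, X))

    def test_single_class_labels_rejected(self, separable):
        X, _ = separable
        with pytest.raises(ValueError, match="both classes"):
            tune_classifier(build_grid("knn"), X, [AIE] * 40)

    def test_tie_breaks_by_grid_order(self, separable):
        X, y = separable
        # both neighbor counts are perfect on this toy set -> first declared wins
        spec = ClassifierSpec("knn", {"n_neighbors": [5, 3]})
        tuned = tune_classifier(spec, X, y, seed=0)
        assert tuned.chosen_params == {"n_neighbors": 5}


class TestPrediction:
    def test_knn_three_neighbor_vote_matches_distance_oracle(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]])
        y = np.array([AIE, AIE, ACQ, ACQ, ACQ, ACQ])
        query = np.array([[0.4, 0.4]])
        # oracle: brute-force Euclidean distances -> 3 nearest are rows 0,1,2
        dists = np.linalg.norm(X - query, axis=1)
        nearest = np.argsort(dists)[:3]
        assert sorted(nearest) == [0, 1, 2]  # 2 AIE vs 1 ACQ
        tuned = tune_classifier(ClassifierSpec("knn", {"n_neighbors": [3]}), X, y, inner_folds=2)
        assert predict_labels(tuned, query)[0] == AIE

    def test_interpolating_model_reproduces_training_labels(self, separable):
        X, y = separable
        tuned = tune_classifier(ClassifierSpec("knn", {"n_neighbors": [3]}), X, y)
        assert (predict_labels(tuned, X) == y).all()

    @pytest.mark.parametrize("family", FAMILIES)
    def test_scores_live_in_unit_interval(self, family, separable, rng):
        X, y = separable
        tuned = tune_classifier(build_grid(family, "reduced"), X, y, seed=0)
        scores = predict_scores(tuned, rng.normal(size=(30, 2)) * 5)
        assert ((scores >= 0.0) & (scores <= 1.0)).all()

    def test_dimension_mismatch_errors(self, separable):
        X, y = separable
        tuned = tune_classifier(ClassifierSpec("knn", {"n_neighbors": [3]}), X, y)
        with pytest.raises(ValueError, match="width"):
            predict_labels(tuned, np.zeros((2, 5)))


def test_estimator_fixed_settings_follow_protocol():
    knn = make_estimator("knn", {"n_neighbors": 5})
    assert knn.metric == "euclidean" and knn.weights == "uniform"
    mlp = make_estimator("mlp", {"alpha": 1e-4}, seed=3)
    assert mlp.hidden_layer_sizes == (100,) and mlp.early_stopping is False
    gb = make_estimator("gradient_boost", {"max_depth": 3})
    assert gb.learning_rate == 0.1
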