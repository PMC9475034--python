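import numpy as np
import pytest

from psnfuse.classify import (
    MLPConfig,
    MLPModel,
    compute_class_weights,
    predict_logits,
    predict_mlp,
    rfe_select,
    train_mlp,
    weighted_cross_entropy,
)


class TestClassWeights:
    @pytest.mark.parametrize(
        "n0,n1,expect",
        [(400, 100, (1.0, 4.0)), (50, 50, (1.0, 1.0)), (77, 23, (1.0, 77 / 23))],
    )
    def test_majority_gets_weight_one(self, n0, n1, expect):
        y = np.array([0] * n0 + [1] * n1)
        w = compute_class_weights(y)
        assert w == pytest.approx(expect)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            compute_class_weights(np.zeros(10, int))


class TestWeightedCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert weighted_cross_entropy(p, [0, 1]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_give_ln2(self):
        p = np.full((20, 2), 0.5)
        y = np.arange(20) % 2
        assert weighted_cross_entropy(p, y) == pytest.approx(np.log(2))

    def test_weights_scale_class_contributions_linearly(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet([1, 1], size=40)
        y = (np.arange(40) % 2).astype(int)
        base = weighted_cross_entropy(p, y, (1.0, 1.0))
        up = weighted_cross_entropy(p, y, (1.0, 2.0))
        # doubling class-1 weight adds exactly the class-1 mean NLL again
        class1 = weighted_cross_entropy(p[y == 1], np.ones((y == 1).sum(), int))
        assert up == pytest.approx(base + 0.5 * class1)

    def test_balanced_weights_equal_unweighted(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet([1, 1], size=30)
        y = (np.arange(30) % 2).astype(int)
        w = compute_class_weights(y)
        assert weighted_cross_entropy(p, y, w) == pytest.approx(
            weighted_cross_entropy(p, y)
        )


class TestTrainPredict:
    def linearly_separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 2).astype(int)
        X = rng.normal(0, 1, (n, 2))
        X[y == 1] += 3.0
        return X, y

    def test_separable_data_high_training_accuracy(self):
        X, y = self.linearly_separable()
        model = train_mlp(X, y, MLPConfig(layer_sizes=(8,), seed=1, max_epochs=200,
                                          patience=10, dropout=0.2))
        pred, prob = predict_mlp(model, X)
        assert (pred == y).mean() >= 0.95
        assert np.all((prob >= 0) & (prob <= 1))

    def test_training_is_deterministic(self):
        X, y = self.linearly_separable(seed=3)
        cfg = MLPConfig(layer_sizes=(4, 4), seed=7, max_epochs=50, dropout=0.5)
        m1, m2 = train_mlp(X, y, cfg), train_mlp(X, y, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))
        assert all(np.array_equal(a, b) for a, b in zip(m1.biases, m2.biases))

    def test_patience_zero_stops_at_first_non_improvement(self):
        X, y = self.linearly_separable(seed=5)
        model = train_mlp(
            X, y, MLPConfig(layer_sizes=(4,), seed=2, max_epochs=200, patience=0)
        )
        log = model.training_log
        assert log["stopped_epoch"] == log["best_epoch"] + 1 or \
            log["stopped_epoch"] == len(log["val_loss"]) - 1

    def test_tie_in_logits_predicts_class_zero(self):
        # weights that always produce equal logits
        model = MLPModel(layer_sizes=(), weights=[np.zeros((3, 2))], biases=[np.zeros(2)])
        pred, prob = predict_mlp(model, np.ones((4, 3)))
        assert np.all(pred == 0)
        assert np.allclose(prob, 0.5)

    def test_width_mismatch_raises(self):
        model = MLPModel(layer_sizes=(), weights=[np.zeros((3, 2))], biases=[np.zeros(2)])
        with pytest.raises(ValueError, match="width"):
            predict_mlp(model, np.ones((2, 5)))

    def test_column_permutation_consistency(self):
        X, y = self.linearly_separable(seed=9)
        model = train_mlp(X, y, MLPConfig(layer_sizes=(6,), seed=4, max_epochs=60,
                                          dropout=0.0))
        perm = [1, 0]
        permuted = MLPModel(
            layer_sizes=model.layer_sizes,
            weights=[model.weights[0][perm]] + [w.copy() for w in model.weights[1:]],
            biases=[b.copy() for b in model.biases],
        )
        assert np.allclose(predict_logits(model, X), predict_logits(permuted, X[:, perm]))


class TestRFE:
    def fixture(self, n=300, d=20, seed=0, effect=2.0):
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 2).astype(int)
        X = rng.normal(0, 1, (n, d))
        X[np.ix_(y == 1, [0, 1])] += effect
        return X, y

    def test_no_elimination_when_all_requested(self):
        X, y = self.fixture()
        res = rfe_select(X, y, "logistic", n_select=X.shape[1], seed=0)
        assert len(res.trace) == 0
        assert np.array_equal(res.selected, np.arange(X.shape[1]))

    @pytest.mark.parametrize("estimator", ["logistic", "decision_tree"])
    def test_iteration_count_and_ranking_permutation(self, estimator):
        X, y = self.fixture(n=120, d=12)
        res = rfe_select(X, y, estimator, n_select=4, seed=1)
        assert len(res.trace) == 12 - 4
        assert sorted(res.ranking.tolist()) == list(range(12))
        assert len(res.selected) == 4

    def test_informative_pair_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            X, y = self.fixture(seed=100 + seed)
            res = rfe_select(X, y, "logistic", n_select=2, seed=seed)
            hits += set(res.selected.tolist()) == {0, 1}
        assert hits >= 9

    def test_agrees_with_sklearn_rfe_on_linear_model(self):
        # independent cross-check: scikit-learn's RFE with step=1
        from sklearn.feature_selection import RFE
        from sklearn.linear_model import LogisticRegression

        X, y = self.fixture(n=150, d=10, seed=42)
        ours = rfe_select(X, y, "logistic", n_select=3, seed=0)
        ref = RFE(LogisticRegression(max_iter=2000), n_features_to_select=3, step=1)
        ref.fit(X, y)
        assert set(ours.selected.tolist()) == set(np.flatnonzero(ref.support_).tolist())

    def test_unknown_estimator(self):
        X, y = self.fixture(n=40, d=5)
        with pytest.raises(ValueError, match="estimator"):
            rfe_select(X, y, "perceptron", 2)
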