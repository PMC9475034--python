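import numpy as np
import pytest

from psnfuse.evaluate import CVReport, compute_metrics, nested_cv, stratified_folds


class TestStratifiedFolds:
    def test_exact_stratification_nine_samples(self):
        y = np.array([0] * 6 + [1] * 3)
        folds = stratified_folds(y, 3, seed=0)
        for _, te in folds:
            assert (y[te] == 0).sum() == 2 and (y[te] == 1).sum() == 1

    def test_partition_properties_and_determinism(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=40)
        y[:5], y[5:10] = 0, 1
        folds = stratified_folds(y, 4, seed=9)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(40))
        for i, (_, te_i) in enumerate(folds):
            for _, te_j in folds[i + 1:]:
                assert not set(te_i) & set(te_j)
        again = stratified_folds(y, 4, seed=9)
        assert all(np.array_equal(a[1], b[1]) for a, b in zip(folds, again))

    def test_class_smaller_than_k_raises(self):
        y = np.array([0] * 10 + [1] * 2)
        with pytest.raises(ValueError):
            stratified_folds(y, 3, seed=0)


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        assert m == {"acc": 1.0, "f1": 1.0, "auc": 1.0}

    def test_all_majority_on_imbalanced_split(self):
        y = np.array([0] * 77 + [1] * 23)
        m = compute_metrics(y, np.zeros(100, int), np.zeros(100))
        assert m["acc"] == pytest.approx(0.77)
        assert m["f1"] == 0.0

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=2000)
        prob = rng.random(2000)
        m = compute_metrics(y, (prob > 0.5).astype(int), prob)
        assert m["auc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_auc_is_missing_not_half(self):
        m = compute_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])
        assert m["auc"] is None

    def test_agrees_with_brute_force_on_tiny_instance(self):
        # enumerate the AUC rank statistic by hand with tie correction
        y = np.array([0, 0, 1, 1, 0])
        prob = np.array([0.1, 0.5, 0.5, 0.9, 0.2])
        pairs, wins = 0, 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                pairs += 1
                wins += 1.0 if prob[i] > prob[j] else 0.5 if prob[i] == prob[j] else 0.0
        m = compute_metrics(y, (prob > 0.5).astype(int), prob)
        assert m["auc"] == pytest.approx(wins / pairs)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0], [0.5])


class RecordingPipeline:
    """Linear-threshold pipeline that records every index it was fitted on."""

    seen = []

    def __init__(self, params):
        self.params = params

    def fit(self, X, y):
        RecordingPipeline.seen.append(np.asarray(X[:, 0]).copy())
        self.w = 1.0 if self.params.get("flip", False) is False else -1.0
        return self

    def predict(self, X):
        score = self.w * X[:, 0]
        return (score > 0).astype(int), 1 / (1 + np.exp(-score))


class TestNestedCV:
    def make_data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 2).astype(int)
        X = rng.normal(0, 1, (n, 3))
        X[y == 1, 0] += 2.5
        X[y == 0, 0] -= 2.5
        # stash the index in column 2 so pipelines can be audited
        X[:, 2] = np.arange(n)
        return X, y

    def factory(self, params):
        return RecordingPipeline(params)

    def test_single_configuration_short_circuits(self):
        X, y = self.make_data()
        report = nested_cv(X, y, self.factory, [{"flip": False}], outer_k=3,
                           inner_k=3, repeats=1, seed=0)
        assert all(f["params"] == {"flip": False} for f in report.folds)
        assert len(report.folds) == 3

    def test_grid_selects_the_better_configuration(self):
        X, y = self.make_data()
        report = nested_cv(X, y, self.factory,
                           [{"flip": False}, {"flip": True}],
                           outer_k=3, inner_k=3, repeats=1, seed=1)
        assert all(f["params"] == {"flip": False} for f in report.folds)
        assert report.summary["acc"]["mean"] > 0.8

    def test_outer_folds_partition_and_inner_never_sees_test(self):
        X, y = self.make_data(n=48, seed=3)

        audit = []

        class AuditPipeline(RecordingPipeline):
            def fit(self, Xf, yf):
                audit.append(set(Xf[:, 2].astype(int).tolist()))
                return super().fit(Xf, yf)

        nested_cv(X, y, lambda p: AuditPipeline(p),
                  [{"flip": False}, {"flip": True}], outer_k=3, inner_k=3,
                  repeats=1, seed=5)
        from psnfuse.evaluate import stratified_folds

        outer = stratified_folds(y, 3, seed=5)
        test_sets = [set(te.tolist()) for _, te in outer]
        # every recorded training set must be disjoint from the outer-test
        # fold it belongs to; outer-test folds partition the samples
        assert set().union(*test_sets) == set(range(48))
        for fitted in audit:
            # each fit happened within some outer-training fold
            assert any(fitted <= (set(range(48)) - ts) for ts in test_sets)

    def test_summary_recomputable_from_folds(self):
        X, y = self.make_data(seed=7)
        report = nested_cv(X, y, self.factory, [{"flip": False}], outer_k=3,
                           inner_k=2, repeats=2, seed=2)
        fresh = report.recompute_summary()
        for metric, stats in report.summary.items():
            assert stats == pytest.approx(fresh[metric])

    def test_report_serializes(self, tmp_path):
        X, y = self.make_data(seed=8)
        report = nested_cv(X, y, self.factory, [{"flip": False}], outer_k=2,
                           inner_k=2, repeats=1, seed=3)
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        payload = json.loads(out.read_text())
        assert "summary" in payload and len(payload["folds"]) == 2
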