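"""Metrics and nested cross-validation for outcome prediction.

Cohorts of a few hundred patients leave no room for a standalone test
set, so generalization is estimated with nested cross-validation: an
inner k-fold grid search on each outer-training fold picks the
hyperparameters, a model with those hyperparameters is refit on the
whole outer-training fold and scored on the untouched outer-test fold,
and the whole procedure repeats over several random splits to give a
mean +/- SD per metric.  All data-dependent fitting (z-scoring included,
via the pipeline objects) happens inside training folds only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CVReport",
    "stratified_folds",
    "compute_metrics",
    "nested_cv",
]

METRICS = ("acc", "f1", "auc")


def stratified_folds(labels, k: int, seed: int = 0):
    """k stratified folds as (train_idx, test_idx) pairs.

    Class proportions are preserved within one sample per fold; folds
    are disjoint and exhaustive, and reproducible under the seed.
    """
    y = np.asarray(labels, int)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(y)), y)]


def compute_metrics(y_true, y_pred, y_prob) -> dict:
    """Accuracy, F1 (positive class = death, label 1) and rank-based ROC-AUC.

    AUC is reported as None when only one class is present in
    ``y_true`` (undefined, deliberately not coerced to 0.5).
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    y_prob = np.asarray(y_prob, float)
    if not (len(y_true) == len(y_pred) == len(y_prob)):
        raise ValueError("y_true, y_pred and y_prob must have equal length")
    out = {
        "acc": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
    }
    if len(np.unique(y_true)) < 2:
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(y_true, y_prob))
    return out


@dataclass
class CVReport:
    """Per-fold nested-CV results plus summary statistics."""

    folds: list  # dicts: repeat, fold, metrics, params, train_idx, test_idx
    summary: dict = field(default_factory=dict)

    def recompute_summary(self) -> dict:
        out = {}
        for m in METRICS:
            vals = [f["metrics"][m] for f in self.folds if f["metrics"][m] is not None]
            if vals:
                out[m] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
            else:
                out[m] = {"mean": None, "sd": None}
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "summary": self.summary,
            "folds": [
                {
                    **{k: v for k, v in f.items() if k not in ("train_idx", "test_idx")},
                    "train_idx": [int(i) for i in f["train_idx"]],
                    "test_idx": [int(i) for i in f["test_idx"]],
                }
                for f in self.folds
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _grid_points(hyper_grid) -> list:
    if isinstance(hyper_grid, dict):
        keys = sorted(hyper_grid)
        return [dict(zip(keys, vals)) for vals in product(*(hyper_grid[k] for k in keys))]
    return [dict(g) for g in hyper_grid]


def _score_fold(pipeline, X, y, tr, te, metric):
    pipeline.fit(X[tr], y[tr])
    pred, prob = pipeline.predict(X[te])
    m = compute_metrics(y[te], pred, prob)
    val = m[metric]
    return m, (-np.inf if val is None else val)


def nested_cv(
    features,
    labels,
    pipeline_factory,
    hyper_grid,
    outer_k: int = 3,
    inner_k: int = 3,
    repeats: int = 3,
    seed: int = 0,
    selection_metric: str = "auto",
) -> CVReport:
    """Nested cross-validation with inner-loop hyperparameter tuning.

    Parameters
    ----------
    pipeline_factory : callable(params: dict) -> pipeline
        The pipeline exposes ``fit(X, y)`` and ``predict(X) -> (labels,
        class-1 probabilities)`` and must do all data-dependent fitting
        (z-scoring, selection) inside ``fit``.
    hyper_grid : dict of lists, or list of dicts
        A single configuration short-circuits the inner loop.
    selection_metric : {"auto", "acc", "f1"}
        "auto" tunes on F1 when the majority class exceeds 60% of the
        samples (F1 is the more honest target under imbalance) and on
        accuracy otherwise.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, int)
    grid = _grid_points(hyper_grid)
    if not grid:
        raise ValueError("hyper_grid must be nonempty")
    if selection_metric == "auto":
        maj = np.bincount(y).max() / len(y)
        selection_metric = "f1" if maj > 0.6 else "acc"

    folds_out = []
    for rep in range(repeats):
        rep_seed = (int(seed) + 104729 * rep) % (2**31 - 1)
        outer = stratified_folds(y, outer_k, seed=rep_seed)
        for fold_i, (tr, te) in enumerate(outer):
            if len(grid) == 1:
                best_params = grid[0]
            else:
                inner = stratified_folds(y[tr], inner_k, seed=rep_seed + 1)
                best_params, best_score = None, -np.inf
                for params in grid:
                    scores = []
                    for itr, ite in inner:
                        _, s = _score_fold(
                            pipeline_factory(params), X[tr], y[tr], itr, ite,
                            selection_metric,
                        )
                        scores.append(s)
                    mean_s = float(np.mean(scores))
                    if mean_s > best_score + 1e-12:
                        best_score, best_params = mean_s, params
            metrics, _ = _score_fold(
                pipeline_factory(best_params), X, y, tr, te, selection_metric
            )
            folds_out.append(
                {
                    "repeat": rep,
                    "fold": fold_i,
                    "metrics": metrics,
                    "params": best_params,
                    "train_idx": tr,
                    "test_idx": te,
                }
            )
    report = CVReport(folds=folds_out)
    report.summary = report.recompute_summary()
    return report
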