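"""Integrated-Gradients attribution and rank-ordered feature abridgement.

Integrated Gradients attributes a model output F to each input feature
as the path integral of the gradient along the straight line from a
baseline x' to the input x:

    IG_i(x) = (x_i - x'_i) * ∫_0^1 ∂F(x' + α (x - x')) / ∂x_i dα

The integral is discretized with a midpoint Riemann sum.  F is the
pre-softmax logit of the model's predicted class (the logit avoids the
gradient saturation of the softmax probability).  The default baseline
is the zero vector: features are z-scored before training, so zero is
the cohort mean — a neutral reference patient.

A per-feature saliency score is the Euclidean norm of its attribution
column across samples.  The abridgement experiment freezes the saliency
ranks computed on the full model and drops the least salient feature
one at a time, retraining with fixed hyperparameters and tracking
held-out metrics, to find the smallest feature subset that preserves
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    MLPConfig,
    MLPModel,
    input_gradients,
    predict_logits,
    predict_mlp,
    train_mlp,
    zscore_apply,
    zscore_fit,
)
from .evaluate import compute_metrics

__all__ = [
    "AttributionResult",
    "AbridgementConfig",
    "integrated_gradients",
    "attribution_matrix",
    "saliency_scores",
    "recursive_abridgement",
]


@dataclass
class AttributionResult:
    attributions: np.ndarray  # n_samples x n_features
    baseline: np.ndarray
    steps: int
    target: np.ndarray  # per-sample class whose logit was attributed
    saliency: np.ndarray


def integrated_gradients(
    model: MLPModel, x, baseline=None, steps: int = 300, target=None
) -> np.ndarray:
    """Midpoint-rule Integrated Gradients for one sample or a batch.

    Parameters
    ----------
    model : MLPModel
    x : array of shape (n_features,) or (n_samples, n_features)
    baseline : same width as x; defaults to zeros.
    steps : int >= 1
        Riemann steps discretizing the path integral.
    target : int array or None
        Class whose logit is differentiated; defaults to the model's
        predicted class per sample (ties resolve to class 0).
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    single = np.asarray(x).ndim == 1
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if baseline is None:
        base = np.zeros_like(X)
    else:
        base = np.broadcast_to(np.asarray(baseline, dtype=float), X.shape).copy()
    if base.shape[-1] != model.n_inputs:
        raise ValueError("baseline width does not match model input width")
    if target is None:
        logits = predict_logits(model, X)
        tgt = np.argmax(logits, axis=1)
    else:
        tgt = np.broadcast_to(np.asarray(target, int), (X.shape[0],))

    diff = X - base
    total = np.zeros_like(X)
    for j in range(steps):
        alpha = (j + 0.5) / steps
        total += input_gradients(model, base + alpha * diff, tgt)
    attr = diff * total / steps
    return attr[0] if single else attr


def attribution_matrix(
    model: MLPModel, X, baseline=None, steps: int = 300, target=None
) -> AttributionResult:
    """Attributions for every sample plus per-feature saliency scores."""
    X = np.asarray(X, dtype=float)
    attr = integrated_gradients(model, X, baseline=baseline, steps=steps, target=target)
    if target is None:
        tgt = np.argmax(predict_logits(model, X), axis=1)
    else:
        tgt = np.broadcast_to(np.asarray(target, int), (X.shape[0],)).copy()
    base = np.zeros(X.shape[1]) if baseline is None else np.asarray(baseline, float)
    return AttributionResult(
        attributions=attr,
        baseline=base,
        steps=steps,
        target=tgt,
        saliency=saliency_scores(attr),
    )


def saliency_scores(attributions) -> np.ndarray:
    """Per-feature Euclidean norm of the attribution column across samples."""
    a = np.atleast_2d(np.asarray(attributions, dtype=float))
    if a.size == 0:
        raise ValueError("attribution matrix must be nonempty")
    return np.linalg.norm(a, axis=0)


@dataclass
class AbridgementConfig:
    metric: str = "f1"  # primary metric for choosing the best subset
    val_fraction: float = 0.3
    steps: int = 300
    seed: int = 0
    mlp: MLPConfig | None = None


def _stratified_split(y, fraction, rng):
    tr, va = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        n_val = max(1, int(round(fraction * len(members))))
        va.extend(members[:n_val])
        tr.extend(members[n_val:])
    return np.sort(np.array(tr, int)), np.sort(np.array(va, int))


def recursive_abridgement(features, labels, config: AbridgementConfig | None = None):
    """Rank-ordered feature removal with retraining.

    Saliency ranks are computed once from a model trained on all
    features and then frozen.  For each retained count from n_features
    down to 1, the least salient features are dropped, the model is
    retrained with the same hyperparameters, and validation metrics are
    recorded.  The best subset maximizes the primary metric; ties go to
    the smaller subset.

    Returns
    -------
    trace : DataFrame with columns (retained, acc, f1, auc, features)
    best_features : ndarray of retained feature indices
    """
    config = config or AbridgementConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, int)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to abridge")
    mlp_cfg = config.mlp or MLPConfig(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    idx_tr, idx_val = _stratified_split(y, config.val_fraction, rng)

    def fit_eval(cols):
        mu, sd = zscore_fit(X[np.ix_(idx_tr, cols)])
        model = train_mlp(zscore_apply(X[np.ix_(idx_tr, cols)], mu, sd), y[idx_tr], mlp_cfg)
        pred, prob = predict_mlp(model, zscore_apply(X[np.ix_(idx_val, cols)], mu, sd))
        return model, mu, sd, compute_metrics(y[idx_val], pred, prob)

    all_cols = np.arange(X.shape[1])
    full_model, mu, sd, _ = fit_eval(all_cols)
    attr = integrated_gradients(
        full_model, zscore_apply(X[idx_tr], mu, sd), steps=config.steps
    )
    order = np.argsort(-saliency_scores(attr), kind="stable")  # most salient first

    rows = []
    best = None
    for retained in range(X.shape[1], 0, -1):
        cols = np.sort(order[:retained])
        _, _, _, metrics = fit_eval(cols)
        rows.append({"retained": retained, **metrics, "features": cols.tolist()})
        score = metrics[config.metric]
        score = -np.inf if score is None or not np.isfinite(score) else score
        # ties go to the smaller subset; retained is scanned descending
        if (
            best is None
            or score > best[0] + 1e-12
            or (abs(score - best[0]) <= 1e-12 and retained < best[1])
        ):
            best = (score, retained, cols)
    trace = pd.DataFrame(rows)
    return trace, best[2]
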