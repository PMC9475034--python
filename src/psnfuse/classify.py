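"""Binary outcome classifiers over network features.

The main classifier is a small feed-forward network (ReLU hidden layers,
softmax output over the two classes) trained with Adam on the
cross-entropy loss, optionally weighted to compensate class imbalance:
``weight_i = max(n_0, n_1) / n_i`` so the majority class always has
weight 1.  Early stopping monitors a stratified validation split held
out of the training data.  The network is implemented directly in numpy
with explicit backpropagation, which keeps the model fully deterministic
under a fixed seed and makes gradients with respect to the *inputs*
(needed for attribution) exact.

The classical alternative is recursive feature elimination (RFE): fit an
estimator, rank the features by |coefficient| (linear models) or
impurity importance (trees), drop exactly the lowest-ranked feature, and
repeat until the requested number remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "MLPModel",
    "MLPConfig",
    "RFEResult",
    "compute_class_weights",
    "weighted_cross_entropy",
    "train_mlp",
    "predict_mlp",
    "predict_logits",
    "input_gradients",
    "rfe_select",
    "zscore_fit",
    "zscore_apply",
]

PROB_CLIP = 1e-12


def compute_class_weights(labels) -> tuple:
    """Imbalance-compensating weights ``weight_i = max(n_0, n_1) / n_i``."""
    y = np.asarray(labels, int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute class weights")
    m = max(n0, n1)
    return (m / n0, m / n1)


def weighted_cross_entropy(probabilities, labels, class_weights=(1.0, 1.0)) -> float:
    """Mean weighted negative log-likelihood of the true class.

    Probabilities are clipped at 1e-12; with unit weights this is the
    plain cross-entropy.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, int)
    if p.ndim != 2 or p.shape[0] != len(y):
        raise ValueError("probabilities must be (n_samples, n_classes) aligned to labels")
    w = np.asarray(class_weights, dtype=float)[y]
    p_true = np.clip(p[np.arange(len(y)), y], PROB_CLIP, 1.0)
    return float(np.mean(-w * np.log(p_true)))


@dataclass
class MLPConfig:
    layer_sizes: tuple = (8, 64, 4, 8)  # hidden widths; () gives a linear softmax model
    lr: float = 0.01
    batch_size: int = 32
    dropout: float = 0.5
    max_epochs: int = 300
    patience: int = 20
    seed: int = 0
    val_fraction: float = 0.1
    class_weighting: str = "auto"  # auto: weight when majority fraction > 0.6


@dataclass
class MLPModel:
    """Feed-forward softmax classifier (weights per layer, 2 output units)."""

    layer_sizes: tuple
    weights: list
    biases: list
    dropout_rate: float = 0.0
    class_weights: tuple = (1.0, 1.0)
    training_log: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: MLPModel, X: np.ndarray, dropout_rng=None):
    """Forward pass; returns (hidden activations list, logits).

    When ``dropout_rng`` is given, inverted dropout is applied to each
    hidden activation and the masks are returned too.
    """
    h = X
    acts, masks = [X], []
    n_layers = len(model.weights)
    for l in range(n_layers - 1):
        z = h @ model.weights[l] + model.biases[l]
        h = np.maximum(z, 0.0)
        if dropout_rng is not None and model.dropout_rate > 0:
            keep = 1.0 - model.dropout_rate
            mask = (dropout_rng.random(h.shape) < keep) / keep
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(h)
    logits = h @ model.weights[-1] + model.biases[-1]
    return acts, masks, logits


def predict_logits(model: MLPModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model input {model.n_inputs}"
        )
    _, _, logits = _forward(model, X)
    return logits


def predict_mlp(model: MLPModel, X):
    """Predict hard labels and class-1 probabilities.

    Dropout is disabled; ties in the logits resolve to class 0.
    """
    logits = predict_logits(model, X)
    probs = _softmax(logits)
    labels = np.argmax(logits, axis=1)  # argmax returns the first (class 0) on ties
    return labels.astype(int), probs[:, 1]


def input_gradients(model: MLPModel, X, target_class) -> np.ndarray:
    """d(logit of target class)/d(input) for each row of X (no dropout)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    target = np.broadcast_to(np.asarray(target_class, int), (X.shape[0],))
    acts, _, logits = _forward(model, X)
    n_layers = len(model.weights)
    # backprop a one-hot on the chosen logit
    g = np.zeros_like(logits)
    g[np.arange(X.shape[0]), target] = 1.0
    grad = g @ model.weights[-1].T
    for l in range(n_layers - 2, -1, -1):
        z_pos = acts[l + 1] > 0  # ReLU gate (post-activation > 0 <=> pre > 0)
        grad = (grad * z_pos) @ model.weights[l].T
    return grad


def _stratified_holdout(y, fraction, rng):
    idx_tr, idx_val = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        n_val = max(1, int(round(fraction * len(members)))) if len(members) > 1 else 0
        idx_val.extend(members[:n_val])
        idx_tr.extend(members[n_val:])
    return np.sort(np.array(idx_tr, int)), np.sort(np.array(idx_val, int))


def train_mlp(features, labels, config: MLPConfig | None = None) -> MLPModel:
    """Train the feed-forward classifier with Adam and early stopping.

    A stratified ``val_fraction`` split of the training data monitors
    the (weighted) validation loss; training stops when the loss has not
    improved for more than ``patience`` epochs and the best-validation
    weights are returned.  Fully reproducible under ``config.seed``.
    """
    config = config or MLPConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features must be (n_samples, n_features) aligned to labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each class")

    if config.class_weighting == "always":
        cw = compute_class_weights(y)
    elif config.class_weighting == "never":
        cw = (1.0, 1.0)
    else:  # auto: only compensate a clear imbalance
        cw = compute_class_weights(y) if counts.max() / len(y) > 0.6 else (1.0, 1.0)

    rng = np.random.default_rng(config.seed)
    sizes = [X.shape[1], *config.layer_sizes, 2]
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[l]), size=(sizes[l], sizes[l + 1]))
        for l in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]
    model = MLPModel(
        layer_sizes=tuple(config.layer_sizes),
        weights=weights,
        biases=biases,
        dropout_rate=config.dropout,
        class_weights=cw,
    )

    idx_tr, idx_val = _stratified_holdout(y, config.val_fraction, rng)
    if len(idx_val) == 0 or len(np.unique(y[idx_tr])) < 2:
        idx_tr, idx_val = np.arange(len(y)), np.arange(len(y))
    Xtr, ytr, Xval, yval = X[idx_tr], y[idx_tr], X[idx_val], y[idx_val]

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    wvec = np.asarray(cw)

    best_loss, best_state, best_epoch = np.inf, None, -1
    log_train, log_val = [], []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = Xtr[batch], ytr[batch]
            acts, masks, logits = _forward(model, xb, dropout_rng=rng)
            probs = _softmax(logits)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            gz = wvec[yb][:, None] * (probs - onehot) / len(yb)

            step += 1
            grad = gz
            for l in range(len(model.weights) - 1, -1, -1):
                gw = acts[l].T @ grad
                gb = grad.sum(axis=0)
                if l > 0:
                    grad = grad @ model.weights[l].T
                    if masks[l - 1] is not None:
                        grad = grad * masks[l - 1]
                    grad = grad * (acts[l] > 0)
                # Adam update
                mw[l] = beta1 * mw[l] + (1 - beta1) * gw
                vw[l] = beta2 * vw[l] + (1 - beta2) * gw**2
                mb[l] = beta1 * mb[l] + (1 - beta1) * gb
                vb[l] = beta2 * vb[l] + (1 - beta2) * gb**2
                mhat = mw[l] / (1 - beta1**step)
                vhat = vw[l] / (1 - beta2**step)
                model.weights[l] -= config.lr * mhat / (np.sqrt(vhat) + eps)
                mhatb = mb[l] / (1 - beta1**step)
                vhatb = vb[l] / (1 - beta2**step)
                model.biases[l] -= config.lr * mhatb / (np.sqrt(vhatb) + eps)

        _, _, tr_logits = _forward(model, Xtr)
        tr_loss = weighted_cross_entropy(_softmax(tr_logits), ytr, cw)
        _, _, val_logits = _forward(model, Xval)
        val_loss = weighted_cross_entropy(_softmax(val_logits), yval, cw)
        if not (np.isfinite(tr_loss) and np.isfinite(val_loss)):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        log_train.append(tr_loss)
        log_val.append(val_loss)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_epoch = epoch
            best_state = (
                [w.copy() for w in model.weights],
                [b.copy() for b in model.biases],
            )
        elif epoch - best_epoch > config.patience:
            break

    if best_state is not None:
        model.weights, model.biases = best_state
    model.training_log = {
        "train_loss": log_train,
        "val_loss": log_val,
        "best_epoch": best_epoch,
        "stopped_epoch": epoch,
    }
    return model


# ---------------------------------------------------------------------------
# z-scoring helpers (fit on training folds only)


def zscore_fit(X):
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def zscore_apply(X, mu, sd):
    return (np.asarray(X, dtype=float) - mu) / sd


class MLPPipeline:
    """fit/predict wrapper that z-scores on fit and trains the MLP."""

    def __init__(self, **config_kwargs):
        self.config_kwargs = config_kwargs
        self.model = None

    def fit(self, X, y):
        self.mu_, self.sd_ = zscore_fit(X)
        self.model = train_mlp(
            zscore_apply(X, self.mu_, self.sd_), y, MLPConfig(**self.config_kwargs)
        )
        return self

    def predict(self, X):
        return predict_mlp(self.model, zscore_apply(X, self.mu_, self.sd_))


# ---------------------------------------------------------------------------
# recursive feature elimination


@dataclass
class RFEResult:
    """Outcome of recursive feature elimination.

    ``ranking`` lists feature indices in elimination order (first
    removed first), with the surviving features appended in ascending
    index order; it is a permutation of all features.  ``trace`` holds
    the estimator's training accuracy after each elimination step.
    """

    ranking: np.ndarray
    selected: np.ndarray
    trace: list


_ESTIMATORS = {
    "svm_linear": lambda seed: SVC(kernel="linear", random_state=seed),
    "logistic": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed
    ),
}


def _importance(est) -> np.ndarray:
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_)).ravel()
    return np.asarray(est.feature_importances_)


def rfe_select(features, labels, estimator: str, n_select: int, seed: int = 0) -> RFEResult:
    """Backward elimination of one feature per refit.

    Repeatedly fits the estimator on the remaining features, ranks them
    (|coefficient| for linear estimators, impurity importance for
    trees), and removes exactly the single lowest-ranked feature until
    ``n_select`` remain.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, int)
    n_features = X.shape[1]
    if not 1 <= n_select <= n_features:
        raise ValueError(f"n_select must be in [1, {n_features}], got {n_select}")
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {sorted(_ESTIMATORS)}")

    remaining = list(range(n_features))
    eliminated, trace = [], []
    it = 0
    while len(remaining) > n_select:
        est = _ESTIMATORS[estimator](int(seed))
        try:
            est.fit(X[:, remaining], y)
        except Exception as exc:  # pragma: no cover - estimator failure path
            raise RuntimeError(f"estimator fit failed at iteration {it}: {exc}") from exc
        trace.append(float(est.score(X[:, remaining], y)))
        imp = _importance(est)
        drop_local = int(np.argmin(imp))  # ties -> lowest index
        eliminated.append(remaining.pop(drop_local))
        it += 1
    ranking = np.array(eliminated + sorted(remaining), dtype=int)
    return RFEResult(ranking=ranking, selected=np.array(sorted(remaining), int), trace=trace)
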