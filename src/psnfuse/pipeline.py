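"""End-to-end orchestration: omics matrices -> fused network features -> report.

The canonical run is:

1. (optional) univariate rank-test prefilter per omics, fit on training
   labels only;
2. one patient similarity network per omics (soft-threshold power picked
   for scale-free topology);
3. fusion — either network-level (SNF, then features of the fused
   network) or feature-level (mean centralities + concatenated module
   one-hots);
4. classification of the binary endpoint with the feed-forward network
   or an RFE-wrapped linear estimator, under nested cross-validation or
   a simple stratified hold-out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import MLPConfig, MLPPipeline, rfe_select
from .evaluate import compute_metrics, nested_cv, stratified_folds
from .fusion import fuse_feature_level, snf_fuse
from .network_features import FeatureConfig, NetworkFeatureTable, assemble_features
from .omics_io import OmicsMatrix, filter_features_ranktest
from .psn import PSNConfig, build_psn

logger = logging.getLogger(__name__)

__all__ = ["extract_fused_features", "holdout_evaluation", "run_nested_cv"]


def extract_fused_features(
    matrices,
    strategy: str = "network",
    psn_config: PSNConfig | None = None,
    feature_config: FeatureConfig | None = None,
    snf_K: int | None = None,
    snf_t: int = 20,
) -> NetworkFeatureTable:
    """Build per-omics PSNs and fuse them into one feature table.

    ``strategy="network"`` fuses the affinities with SNF and extracts
    features from the consensus network; ``strategy="feature"`` extracts
    features per network and fuses the tables.
    """
    matrices = list(matrices)
    psn_config = psn_config or PSNConfig()
    feature_config = feature_config or FeatureConfig()
    psns = [build_psn(x, psn_config) for x in matrices]
    for p in psns:
        logger.info("%s: beta=%d scale-free fit=%.3f", p.omics_name, p.beta, p.fit_r2)
    if len(psns) == 1:
        return assemble_features(psns[0], feature_config)
    if strategy == "network":
        fused = snf_fuse(psns, K=snf_K, t=snf_t)
        return assemble_features(fused.to_psn(), feature_config)
    if strategy == "feature":
        tables = [assemble_features(p, feature_config) for p in psns]
        return fuse_feature_level(tables)
    raise ValueError(f"unknown fusion strategy {strategy!r}")


def holdout_evaluation(
    matrices,
    labels,
    strategy: str = "network",
    test_fraction: float = 1 / 3,
    prefilter_alpha: float | None = None,
    mlp_config: MLPConfig | None = None,
    feature_config: FeatureConfig | None = None,
    psn_config: PSNConfig | None = None,
    seed: int = 0,
):
    """Single stratified train/test split through the full pipeline.

    The supervised prefilter (when enabled) sees training labels only;
    network construction and module detection are unsupervised and use
    all patients (the transductive setting natural to patient networks).

    Returns ``(metrics dict, NetworkFeatureTable, test_idx)``.
    """
    y = np.asarray(labels, int)
    k = max(2, int(round(1 / test_fraction)))
    folds = stratified_folds(y, k, seed=seed)
    train_idx, test_idx = folds[0]

    if prefilter_alpha is not None:
        kept = []
        for x in matrices:
            sub = OmicsMatrix(
                values=x.values[train_idx],
                patient_ids=x.patient_ids[train_idx],
                feature_ids=x.feature_ids,
                omics_name=x.omics_name,
            )
            filtered = filter_features_ranktest(sub, y[train_idx], alpha=prefilter_alpha)
            keep_ids = set(filtered.feature_ids)
            mask = np.array([f in keep_ids for f in x.feature_ids])
            kept.append(x.select_features(np.flatnonzero(mask)))
        matrices = kept

    table = extract_fused_features(
        matrices,
        strategy=strategy,
        psn_config=psn_config,
        feature_config=feature_config,
    )
    cfg = mlp_config or MLPConfig(seed=seed)
    pipe = MLPPipeline(**{f: getattr(cfg, f) for f in cfg.__dataclass_fields__})
    pipe.fit(table.values[train_idx], y[train_idx])
    pred, prob = pipe.predict(table.values[test_idx])
    return compute_metrics(y[test_idx], pred, prob), table, test_idx


def run_nested_cv(
    table: NetworkFeatureTable,
    labels,
    hyper_grid=None,
    outer_k: int = 3,
    inner_k: int = 3,
    repeats: int = 3,
    seed: int = 0,
):
    """Nested CV of the feed-forward classifier on a feature table."""
    if hyper_grid is None:
        hyper_grid = {
            "layer_sizes": [(8, 64, 4, 8), (4, 4, 4)],
            "batch_size": [8, 32],
        }
    y = np.asarray(labels, int)

    def factory(params):
        return MLPPipeline(seed=seed, **params)

    return nested_cv(
        table.values,
        y,
        factory,
        hyper_grid,
        outer_k=outer_k,
        inner_k=inner_k,
        repeats=repeats,
        seed=seed,
    )
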