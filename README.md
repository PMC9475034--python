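# psnfuse

Network-based integration of multi-omics data for binary clinical-outcome
prediction.

High-dimensional omics matrices (expression, methylation, ...) measured on
the same patient cohort are hard to combine directly: each omics type has
its own scale, noise structure, and tens of thousands of features for at
most a few hundred patients.  `psnfuse` sidesteps both problems by moving
from feature space to *patient similarity networks* (PSNs): each omics
type becomes a weighted graph over the same patients, and heterogeneous
omics types become homogeneous objects that can be fused and summarized by
a handful of topological features per patient.

## Method

For omics type *m* with patient profiles φ<sup>m</sup><sub>v</sub>, the PSN
is the complete weighted graph G<sup>m</sup> = (V, A<sup>m</sup>) with
affinities a<sup>m</sup><sub>uv</sub> = ((1 + r<sub>uv</sub>) / 2)<sup>β</sup>,
where r<sub>uv</sub> is the Pearson correlation of the two patients'
profiles and the soft-threshold power β is the smallest integer (grid
1–20) whose network reaches a truncated scale-free topology fit
R² ≥ 0.9, following weighted-correlation-network (WGCNA) practice.

Two fusion routes combine the per-omics networks:

* **network-level** — similarity network fusion (SNF): each affinity is
  converted to a full transition kernel P (rows sum to 1, half the mass on
  the diagonal) and a K-nearest-neighbor kernel S, and the kernels
  cross-diffuse, P<sub>v</sub> ← S<sub>v</sub> · mean<sub>u≠v</sub>(P<sub>u</sub>) · S<sub>v</sub>ᵀ,
  for *t* iterations; features are then extracted from the consensus
  network.
* **feature-level** — features are extracted per network; the 13
  centrality columns are averaged across omics and the module one-hot
  blocks are concatenated.

From any network, each patient gets 13 centrality scores (weighted
degree, closeness, current-flow closeness/betweenness, eigenvector, Katz,
HITS authority/hub, PageRank, load, weighted clustering, and iterative
peeling variants of degree and clustering) plus one-hot module
memberships from spectral clustering and a weighted stochastic block
model, with module counts chosen by silhouette score.

The binary endpoint ("death from disease") is predicted by a small
feed-forward softmax network (ReLU, dropout, Adam, early stopping) with
class-weighted cross-entropy, weight<sub>i</sub> = max(n₀, n₁)/nᵢ, under
class imbalance, or by RFE-wrapped linear/tree estimators.  Feature
relevance is quantified with Integrated Gradients,
IG<sub>i</sub>(x) = (x<sub>i</sub> − x′<sub>i</sub>) ∫₀¹ ∂F/∂x<sub>i</sub> (x′ + α(x − x′)) dα,
and a recursive abridgement loop drops low-saliency features one at a
time to find a minimal feature subset.  Generalization is estimated with
nested (3×3) cross-validation.

No real cohort is required: `psnfuse.synthetic_data` generates
multi-omics cohorts with known informative features, planted-block
affinities and preferential-attachment graphs for every experiment.

## Worked example

```python
from psnfuse import SyntheticSpec, generate_multiomics, holdout_evaluation

spec = SyntheticSpec(
    n_patients=150, dims=[300, 300], n_informative=50,
    effect_size=2.0, imbalance=0.55, mode="heterogeneous", seed=11,
)
cohort = generate_multiomics(spec)
metrics, table, test_idx = holdout_evaluation(
    cohort.matrices, cohort.labels, strategy="network", seed=1
)
print("feature table:", table.values.shape)
print("held-out metrics:", metrics)
```

prints

```
feature table: (150, 17)
held-out metrics: {'acc': 1.0, 'f1': 1.0, 'auc': 1.0}
```

Two simulated omics types (300 features each, 50 carrying a 2-SD
class shift) were reduced from 600 raw features to a 17-column network
feature table — 13 centralities plus 2 spectral and 2 SBM module
indicators of the SNF-fused network — on which the classifier labels
every held-out patient correctly.  The same flow is available from the
shell via the `psnfuse` command (`simulate`, `filter`, `build-psn`,
`features`, `fuse`, `classify`, `explain`, `run`).

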