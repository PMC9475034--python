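# Methods

This note records the modelling choices behind `psnfuse`, the defaults
and why they were picked, what the synthetic data does and does not
emulate, and the numerical corner cases.

## Patient similarity networks

Patient similarity is the Pearson correlation of two patients' feature
profiles within one omics type.  Correlations are rescaled to positive
edge weights with the **signed** WGCNA transform a = ((1 + r)/2)^β.  The
signed form was chosen over |r|^β because it keeps anti-correlated
patients (r = −1 → a = 0) distinct from uncorrelated ones (r = 0 →
a = 2^−β); with the unsigned form both would collapse together or, worse,
r = −1 would map to maximal affinity.  The diagonal is zeroed (no
self-similarity) and the complete weighted graph is kept — no hard
sparsification — because the current-flow centralities downstream need a
connected conductance network.

β is selected as the smallest integer in 1…20 whose network reaches a
truncated scale-free topology fit of R² ≥ 0.9.  The fit index bins node
connectivities k_u = Σ_v a_uv into 10 equal-width bins and regresses
log₁₀(bin frequency) on log₁₀(mean bin connectivity) plus the mean
connectivity itself (the truncation term).  The R² is reported only when
the log-connectivity slope is negative — a scale-free law is a
*decreasing* power law — and degenerate inputs (all connectivities equal,
fewer than three occupied bins) score 0.  The bin count (10) and the grid
(integers 1–20) are conventional WGCNA settings; neither is prescribed by
a data-derived quantity.  When no power qualifies, the β maximizing the
fit is used and a warning is logged; correlation networks of strongly
clustered cohorts frequently top out below 0.9 because their connectivity
distribution is multi-modal rather than power-law, and refusing to build
a network in that case would be worse than accepting the best available
power.

## Network features

The centrality block has 13 fixed columns: weighted degree, closeness,
current-flow closeness, current-flow betweenness, eigenvector, Katz, HITS
authority, HITS hub (equal to authority on undirected graphs, kept as a
separate column so the block width is stable), PageRank, load, local
clustering, iterative weighted degree, iterative clustering.  Distance
measures (closeness, load) treat an edge of weight w as length 1/w;
current-flow measures treat w as a conductance; spectral measures act on
the weight matrix.  Weighted clustering uses the geometric-mean (Onnela)
formula — the standard weighted generalization.  Katz attenuation is
α = 0.9/λ_max of the affinity, which guarantees convergence for any
input.

The two *iterative* measures use a minimum-peeling scheme generalizing
k-core ranking to weighted measures: compute the base measure on the
remaining subgraph, record the value for the node(s) attaining the
minimum (within 1e−9), remove them, repeat.  A node's score is its value
at removal, so it reflects standing among progressively more central
company.  Ties are removed together, which makes the scheme well-defined
on symmetric graphs (a complete graph is peeled in one round).

Modules come from two clusterings.  Spectral clustering embeds patients
in the row-normalized eigenvectors of the k smallest eigenvalues of the
symmetric-normalized Laplacian and runs k-means with 10 restarts and a
fixed seed.  The stochastic block model variant fits a Gaussian-weight
SBM — block-pair mean weights with unit variance, whose profile
likelihood reduces to maximizing Σ_{r≤s} S²_rs/N_rs — by greedy
single-node moves from the spectral initialization; accepted moves
strictly increase the objective, blocks are never emptied, and the loop
stops at the first pass without a move (cap 50 passes).  This is a
deliberately simple weighted SBM, not nested-model inference.

The module count for each algorithm is chosen by mean silhouette on the
spectral embedding (Euclidean), scanned over a geometric grid 2, 4, 8, …,
⌊n/2⌋ and refined by ±1 around the best value; ties go to the smaller k.
The silhouette is computed on the embedding rather than the raw affinity
so scores are comparable across algorithms and k.  Both one-hot blocks
are concatenated (each patient contributes one membership per
clustering), giving table width 13 + k_spectral + k_sbm.

## Fusion

SNF consumes the WGCNA-rescaled affinities directly rather than
rebuilding distances with the original exponential kernel: the method
fuses the networks the pipeline actually built.  The full kernel puts
half the transition mass on the node itself (P_ii = 1/2) and distributes
the rest proportionally to affinity; the local kernel keeps each row's K
largest off-diagonal entries (ties broken toward the lower patient index
for determinism) renormalized to sum 1.  Updates are simultaneous across
sources, rows are renormalized each iteration, and the fused network is
the average of the final kernels, symmetrized, diagonal zeroed.  Defaults
K = min(20, n−1) and t = 20 are the SNF authors' customary settings.  A
property worth knowing: prolonged diffusion homogenizes weights within
clusters, so with large t the fused network preserves coarse (cluster)
structure but not the fine ordering of individual edge weights; rank
preservation holds at moderate t on structured networks.

Feature-level fusion averages the 13 centrality columns across omics and
concatenates the module blocks with source-tagged column names.  Feature
tables are z-scored before classification, with means and SDs fit on
training rows only.

## Classification

The feed-forward classifier is written directly in numpy (explicit
backpropagation, Adam with β₁ = 0.9, β₂ = 0.999), which keeps training
bit-reproducible under a fixed seed and makes input gradients — needed
for attribution — exact rather than approximated.  The output layer is a
2-unit softmax; predicted label is the argmax with ties resolving to
class 0; probabilities are clipped at 1e−12 inside the loss.  Defaults:
hidden sizes (8, 64, 4, 8) — the stronger of the two reference
architectures, and the more robust one under heavy dropout since width-4
bottlenecks with rate-0.5 dropout can under-train — learning rate 0.01,
batch 32, dropout 0.5, at most 300 epochs.  Early stopping monitors the
weighted cross-entropy on a 10% stratified split of the training data
with patience 20 and restores the best-validation weights.  Class
weighting (weight_i = max(n₀,n₁)/n_i, majority weight exactly 1) is
applied automatically only when the majority class exceeds 60% of
samples; on balanced data the weighted loss is identical to the plain
one.

RFE removes exactly one feature per refit, ranked by |coefficient| for
linear estimators (linear-kernel SVM, logistic regression) or impurity
importance for trees (decision tree, random forest); argmin tie-breaks
toward the lower feature index.  The estimators themselves are
scikit-learn models; the elimination loop is this package's.

## Relevance

Integrated Gradients discretizes the path integral with a midpoint
Riemann sum (default 300 steps; midpoint halves the bias of the
left-endpoint rule on piecewise-linear ReLU surfaces).  F is the logit of
the predicted class, not the softmax probability — softmax saturates and
flattens gradients precisely for confidently classified samples.  The
baseline is the zero vector: features are z-scored, so zero is the cohort
mean, a neutral "average patient" reference.  For linear models the
attribution is exact at any step count; for trained ReLU networks the
completeness identity Σ_i IG_i = F(x) − F(x′) holds to well under 1% at
300 steps on typical samples (relative error can look larger on samples
whose output barely differs from the baseline's).

Saliency is the L2 norm of each feature's attribution column across
samples (L2 rather than L1: it matches the "magnitude of the attribution
vector" reading and damps sign cancellation identically).  The
abridgement loop computes saliency once on the full model and freezes the
ranks, then retrains with fixed hyperparameters for every retained count
from n down to 1 and records validation accuracy/F1/AUC; the best subset
maximizes the primary metric with ties to the smaller subset.  Frozen
ranks keep the experiment at O(n) trainings; recomputing ranks after each
removal would be O(n) attribution passes more expensive and changes the
semantics from "rank once, prune" to a greedy wrapper.

## Evaluation

Nested cross-validation uses stratified 3-fold outer and inner loops by
default, repeated over 3 random splits to populate the ± SD.  The inner
loop selects hyperparameters by mean inner-fold score; the selection
metric is F1 when the majority class exceeds 60% (accuracy is
uninformative under imbalance) and accuracy otherwise.  A singleton grid
short-circuits the inner loop.  AUC is reported as missing — not 0.5 —
when a test fold contains one class only.

## Synthetic data

The generator emulates two study designs: a *homogeneous* pair (two
technologies re-measuring the same molecular layer — one shared latent
informative block plus independent per-omics measurement noise) and a
*heterogeneous* pair (distinct layers — independent informative blocks).
Features are Gaussian with SD `noise_sd` (default 1); informative
features add a class-1 mean shift of `effect_size · noise_sd`; the
default imbalance 0.77 mirrors a high-survival cohort.  Label counts
follow the imbalance exactly by rounding, informative indices are
returned as ground truth, and all randomness flows from the required
seed.

What the generator does **not** emulate: count distributions of RNA-seq,
beta-value methylation, feature–feature correlation blocks within the
background, batch effects, or missingness.  Passing tests therefore
demonstrate that the pipeline's machinery is correct and recovers planted
structure under Gaussian noise — not that real cohorts of this size reach
any particular accuracy.

Fixture sizes used by the tests and the acceptance script were chosen
once as representative desk-scale conditions: the end-to-end fusion
cohort uses n = 150 patients (a typical high-risk cohort size) with two omics
of 300 features and 50 informative at effect size 2.0 and mild imbalance
0.55; the prefilter study uses n = 100 with 1000 features and 50
informative at the same effect; planted-block module fixtures use n = 60.
The β-selection fixture uses correlated patient blocks of uneven sizes
with per-patient signal strength, because only connectivity-heterogeneous
networks admit a scale-free fit — equal-size blocks produce bimodal
connectivity for which every power is (correctly) rejected and the
fallback engages.

## Known limitations

* The SBM is single-level with a fixed k per fit; no nested or
  degree-corrected variants.
* PSN construction and module detection are transductive (they see all
  patients, unsupervised); only supervised steps — prefilter, z-scoring,
  classifier — are restricted to training folds.
* The scale-free target of 0.9 is often unreachable on strongly clustered
  correlation networks; the fallback to the best-fitting power is logged
  but changes no error status.
* Probabilities are uncalibrated; endpoints are strictly binary.
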