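"""Topological features of a patient similarity network.

Two feature families are extracted per network and concatenated:

* **Centrality** — 13 per-node scores quantifying a patient's position
  in the network (degree-, distance-, flow- and spectrum-based, plus
  two "iterative" peeling variants).  The column order is fixed and
  documented in :data:`CENTRALITY_NAMES`.
* **Modularity** — one-hot encodings of the patient's module membership
  under two clusterings of the network (spectral clustering of the
  normalized Laplacian, and a weighted stochastic block model), each
  with its module count chosen by the silhouette score.

Distance-based measures (closeness, load) interpret an edge of weight w
as having length 1/w; current-flow measures treat w as a conductance;
spectral measures (eigenvector, Katz, HITS, PageRank) act on the weight
matrix itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .psn import PSN, _as_affinity

logger = logging.getLogger(__name__)

__all__ = [
    "CENTRALITY_NAMES",
    "NetworkFeatureTable",
    "FeatureConfig",
    "compute_centralities",
    "iterative_measure",
    "spectral_embedding",
    "spectral_modules",
    "sbm_modules",
    "sbm_objective",
    "select_k_by_silhouette",
    "encode_membership",
    "assemble_features",
    "default_k_grid",
]

#: Fixed order of the centrality block columns.
CENTRALITY_NAMES = [
    "weighted_degree",
    "closeness",
    "current_flow_closeness",
    "current_flow_betweenness",
    "eigenvector",
    "katz",
    "hits_authority",
    "hits_hub",
    "pagerank",
    "load",
    "clustering",
    "iterative_weighted_degree",
    "iterative_clustering",
]


@dataclass
class NetworkFeatureTable:
    """Per-patient network features with per-column provenance tags.

    ``column_meta[j]`` is ``"centrality:<name>"`` or
    ``"modularity:<algorithm>:<module-index>"`` (optionally prefixed by
    a source label after feature-level fusion).
    """

    values: np.ndarray
    patient_ids: np.ndarray
    column_meta: list
    source: str = "psn"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.column_meta) != self.values.shape[1]:
            raise ValueError("column_meta length must equal column count")
        if len(self.patient_ids) != self.values.shape[0]:
            raise ValueError("patient_ids length must equal row count")

    @property
    def centrality_block(self) -> np.ndarray:
        mask = np.array(["centrality:" in m for m in self.column_meta])
        return self.values[:, mask]

    @property
    def modularity_block(self) -> np.ndarray:
        mask = np.array(["modularity:" in m for m in self.column_meta])
        return self.values[:, mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=self.column_meta
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "patient_id"
        df.to_csv(path, sep="\t")


@dataclass
class FeatureConfig:
    k_grid: tuple | None = None  # None -> geometric auto grid
    seed: int = 0
    refine: bool = True


# ---------------------------------------------------------------------------
# centralities


def _require_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        comps = [sorted(c)[:3] for c in nx.connected_components(g)]
        raise ValueError(
            f"graph is disconnected ({len(comps)} components, e.g. {comps[:3]})"
        )


def _to_graph(g) -> nx.Graph:
    if isinstance(g, PSN):
        return g.to_graph()
    if isinstance(g, nx.Graph):
        h = nx.Graph()
        h.add_nodes_from(g.nodes())
        for u, v, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            if w > 0:
                h.add_edge(u, v, weight=w, length=1.0 / w)
        return h
    a = _as_affinity(g)
    return PSN(affinity=a, patient_ids=np.arange(a.shape[0])).to_graph()


def _weighted_degree(g: nx.Graph) -> dict:
    return dict(g.degree(weight="weight"))


def _clustering(g: nx.Graph) -> dict:
    # geometric-mean (Onnela) weighted clustering
    return nx.clustering(g, weight="weight")


def _hits_symmetric(g: nx.Graph, nodes) -> np.ndarray:
    """HITS scores of an undirected graph: the Perron vector of the
    weight matrix, 1-normalized (authority = hub by symmetry)."""
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, -1])
    s = v.sum()
    return v / s if s > 0 else v


def compute_centralities(g) -> np.ndarray:
    """13-column centrality matrix in :data:`CENTRALITY_NAMES` order."""
    h = _to_graph(g)
    _require_connected(h)
    nodes = sorted(h.nodes())
    n = len(nodes)

    lam_max = float(np.linalg.eigvalsh(nx.to_numpy_array(h, nodelist=nodes, weight="weight"))[-1])
    alpha = 0.9 / lam_max if lam_max > 0 else 0.1

    cols = {}
    cols["weighted_degree"] = _weighted_degree(h)
    cols["closeness"] = nx.closeness_centrality(h, distance="length")
    cols["current_flow_closeness"] = nx.current_flow_closeness_centrality(
        h, weight="weight"
    )
    if n > 2:
        cols["current_flow_betweenness"] = nx.current_flow_betweenness_centrality(
            h, weight="weight"
        )
    else:
        cols["current_flow_betweenness"] = {u: 0.0 for u in nodes}
    cols["eigenvector"] = nx.eigenvector_centrality_numpy(h, weight="weight")
    cols["katz"] = nx.katz_centrality_numpy(h, alpha=alpha, weight="weight")
    hits = _hits_symmetric(h, nodes)
    cols["hits_authority"] = {u: hits[i] for i, u in enumerate(nodes)}
    cols["hits_hub"] = dict(cols["hits_authority"])
    cols["pagerank"] = nx.pagerank(h, weight="weight")
    cols["load"] = nx.load_centrality(h, weight="length")
    cols["clustering"] = _clustering(h)
    cols["iterative_weighted_degree"] = iterative_measure(h, base="weighted_degree")
    cols["iterative_clustering"] = iterative_measure(h, base="clustering")

    out = np.empty((n, len(CENTRALITY_NAMES)))
    for j, name in enumerate(CENTRALITY_NAMES):
        col = cols[name]
        out[:, j] = [float(col[u]) for u in nodes]
    return out


_BASE_MEASURES = {"weighted_degree": _weighted_degree, "clustering": _clustering}


def iterative_measure(g, base: str = "weighted_degree", tol: float = 1e-9) -> dict:
    """Peeling ("k-core style") variant of a base nodal measure.

    The base measure is computed on the remaining subgraph; the node(s)
    attaining the minimum (within ``tol``) are assigned that value and
    removed; the process repeats until the graph is empty.  A node's
    iterative score is the value it held at its removal, so the score
    reflects a node's standing among progressively more central company.
    """
    if base not in _BASE_MEASURES:
        raise ValueError(f"unsupported base measure {base!r}")
    fn = _BASE_MEASURES[base]
    h = _to_graph(g).copy()
    scores = {}
    while h.number_of_nodes() > 0:
        vals = fn(h)
        mn = min(vals.values())
        at_min = [u for u, v in vals.items() if v <= mn + tol]
        for u in at_min:
            scores[u] = float(vals[u])
        h.remove_nodes_from(at_min)
    return scores


# ---------------------------------------------------------------------------
# modules


def spectral_embedding(affinity, k: int) -> np.ndarray:
    """Row-normalized eigenvectors of the k smallest eigenvalues of the
    symmetric-normalized Laplacian."""
    a = _as_affinity(affinity)
    n = a.shape[0]
    d = a.sum(axis=1)
    d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    lap = np.eye(n) - d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    lap = (lap + lap.T) / 2
    _, vecs = sla.eigh(lap, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vecs / norms


def _check_k(n: int, k: int) -> None:
    if not 2 <= k <= n - 1:
        raise ValueError(f"module count k must satisfy 2 <= k <= n-1, got {k}")


def spectral_modules(g, k: int, seed: int = 0) -> np.ndarray:
    """Spectral clustering of the affinity into k modules (hard labels)."""
    a = _as_affinity(g)
    _check_k(a.shape[0], k)
    emb = spectral_embedding(a, k)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    return km.fit_predict(emb).astype(int)


def sbm_objective(affinity, labels, k: int) -> float:
    """Profile log-likelihood (up to constants) of a Gaussian-weight SBM.

    With unit weight variance and per-block-pair mean weights, maximizing
    the likelihood over the means reduces to maximizing
    ``sum_{r<=s} S_rs^2 / N_rs`` where ``S_rs`` is the total weight and
    ``N_rs`` the number of node pairs between blocks r and s.
    """
    a = _as_affinity(affinity)
    labels = np.asarray(labels, int)
    q = 0.0
    sizes = np.bincount(labels, minlength=k)
    for r in range(k):
        mr = labels == r
        for s in range(r, k):
            ms = labels == s
            if r == s:
                n_pairs = sizes[r] * (sizes[r] - 1) / 2
                w = a[np.ix_(mr, mr)].sum() / 2
            else:
                n_pairs = sizes[r] * sizes[s]
                w = a[np.ix_(mr, ms)].sum()
            if n_pairs > 0:
                q += w * w / n_pairs
    return float(q)


def sbm_modules(g, k: int, seed: int = 0, max_passes: int = 50) -> np.ndarray:
    """Weighted stochastic block model clustering by greedy label moves.

    Fits a Gaussian-weight SBM (block-pair mean weights, unit variance)
    by hill-climbing single-node moves from a spectral initialization.
    Each accepted move strictly increases the profile likelihood, so the
    final objective is never below the initial one.  Blocks are never
    emptied, keeping exactly k modules available.
    """
    a = _as_affinity(g)
    n = a.shape[0]
    _check_k(n, k)
    labels = spectral_modules(a, k, seed=seed).copy()
    # ensure all k blocks are populated at the start
    rng = np.random.default_rng(seed)
    for r in range(k):
        if not np.any(labels == r):
            donor_blocks = np.bincount(labels, minlength=k)
            donor = int(np.argmax(donor_blocks))
            cand = np.flatnonzero(labels == donor)
            labels[rng.choice(cand)] = r

    sizes = np.bincount(labels, minlength=k).astype(float)
    # S[r, s]: total weight between blocks (S[r, r] counts each pair once)
    S = np.zeros((k, k))
    for r in range(k):
        mr = labels == r
        for s in range(r, k):
            ms = labels == s
            if r == s:
                S[r, r] = a[np.ix_(mr, mr)].sum() / 2
            else:
                S[r, s] = S[s, r] = a[np.ix_(mr, ms)].sum()

    def pair_count(r, s, sz):
        return sz[r] * (sz[r] - 1) / 2 if r == s else sz[r] * sz[s]

    def contrib(S_, sz, blocks):
        # objective terms for block pairs touching the given blocks
        tot = 0.0
        seen = set()
        for r in blocks:
            for s in range(k):
                key = (min(r, s), max(r, s))
                if key in seen:
                    continue
                seen.add(key)
                npair = pair_count(key[0], key[1], sz)
                if npair > 0:
                    tot += S_[key] ** 2 / npair
        return tot

    def move_state(S_, sz, w_u, cur, b):
        # remove u from cur then insert into b; a[u, u] = 0 so w_u[cur]
        # already excludes u and stays valid after removal
        S2, sz2 = S_.copy(), sz.copy()
        S2[cur, cur] -= w_u[cur]
        for r in range(k):
            if r != cur:
                S2[cur, r] -= w_u[r]
                S2[r, cur] = S2[cur, r]
        sz2[cur] -= 1
        S2[b, b] += w_u[b]
        for r in range(k):
            if r != b:
                S2[b, r] += w_u[r]
                S2[r, b] = S2[b, r]
        sz2[b] += 1
        return S2, sz2

    tol = 1e-10
    for _ in range(max_passes):
        moved = False
        for u in range(n):
            cur = int(labels[u])
            if sizes[cur] <= 1:
                continue  # never empty a block
            w_u = np.array([a[u, labels == r].sum() for r in range(k)])
            best_b, best_gain, best_state = cur, 0.0, None
            for b in range(k):
                if b == cur:
                    continue
                S_new, sz_new = move_state(S, sizes, w_u, cur, b)
                blocks = {cur, b}
                gain = contrib(S_new, sz_new, blocks) - contrib(S, sizes, blocks)
                if gain > best_gain + tol:
                    best_gain, best_b, best_state = gain, b, (S_new, sz_new)
            if best_b != cur:
                labels[u] = best_b
                S, sizes = best_state
                moved = True
        if not moved:
            break
    return labels.astype(int)


def select_k_by_silhouette(g, algorithm, k_grid, seed: int = 0):
    """Choose a module count by mean silhouette on the spectral embedding.

    ``algorithm`` is ``"spectral"``, ``"sbm"`` or a callable
    ``(affinity, k, seed) -> labels``.  Ties go to the smaller k.
    Returns ``(k_best, labels_best)``.
    """
    a = _as_affinity(g)
    n = a.shape[0]
    ks = sorted({int(k) for k in k_grid})
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_grid must be a nonempty subset of [2, {n - 1}]")
    fn = {"spectral": spectral_modules, "sbm": sbm_modules}.get(algorithm, algorithm)
    best = None
    for k in ks:
        labels = fn(a, k, seed)
        emb = spectral_embedding(a, k)
        if len(np.unique(labels)) < 2:
            score = -1.0
        else:
            score = float(silhouette_score(emb, labels, metric="euclidean"))
        if best is None or score > best[0] + 1e-12:
            best = (score, k, labels)
    return best[1], best[2]


def encode_membership(labels, k: int) -> np.ndarray:
    """One-hot membership matrix (patients x k)."""
    labels = np.asarray(labels, int)
    if labels.min(initial=0) < 0 or (labels >= k).any():
        raise ValueError("labels must lie in {0..k-1}")
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def default_k_grid(n: int) -> tuple:
    """Geometric grid 2, 4, 8, ... up to floor(n/2)."""
    ks, k = [], 2
    top = max(2, n // 2)
    while k <= top and k <= n - 1:
        ks.append(k)
        k *= 2
    return tuple(ks) or (2,)


def _select_k_refined(a, algorithm, k_grid, seed, refine):
    n = a.shape[0]
    k0, labels0 = select_k_by_silhouette(a, algorithm, k_grid, seed)
    if not refine:
        return k0, labels0
    extra = [k for k in (k0 - 1, k0 + 1) if 2 <= k <= n - 1 and k not in set(k_grid)]
    if not extra:
        return k0, labels0
    return select_k_by_silhouette(a, algorithm, sorted(set(k_grid) | {k0} | set(extra)), seed)


def assemble_features(g, config: FeatureConfig | None = None) -> NetworkFeatureTable:
    """Concatenate the centrality block with one-hot module blocks.

    Module counts for the spectral and SBM clusterings are selected
    independently on a geometric k grid (refined by +-1 around the best),
    so the table width is ``13 + k_spectral + k_sbm``.
    """
    config = config or FeatureConfig()
    if isinstance(g, PSN):
        a, ids, src = g.affinity, g.patient_ids, g.omics_name
    else:
        a = _as_affinity(g)
        ids, src = np.arange(a.shape[0]).astype(object), "psn"
    n = a.shape[0]
    grid = config.k_grid or default_k_grid(n)

    cents = compute_centralities(g if isinstance(g, PSN) else a)
    blocks = [cents]
    meta = [f"centrality:{name}" for name in CENTRALITY_NAMES]
    for alg in ("spectral", "sbm"):
        k, labels = _select_k_refined(a, alg, grid, config.seed, config.refine)
        blocks.append(encode_membership(labels, k))
        meta.extend(f"modularity:{alg}:{j}" for j in range(k))
        logger.info("%s: %s clustering selected k=%d", src, alg, k)
    return NetworkFeatureTable(
        values=np.hstack(blocks), patient_ids=np.asarray(ids), column_meta=meta, source=src
    )
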