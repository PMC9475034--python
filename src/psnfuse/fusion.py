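"""Multi-omics integration at the network or the feature level.

Network-level fusion merges the per-omics patient similarity networks
into one consensus network with similarity network fusion (SNF): each
affinity matrix is converted to a full transition kernel P and a sparse
K-nearest-neighbor kernel S, then the kernels cross-diffuse for t
iterations (each network is updated through its local kernel using the
average of the other networks' global kernels), and the final networks
are averaged and symmetrized.

Feature-level fusion instead merges the per-network feature tables:
the 13 centrality columns are averaged across omics and the module
one-hot blocks are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_features import CENTRALITY_NAMES, NetworkFeatureTable
from .psn import PSN, _as_affinity

__all__ = [
    "FusedAffinity",
    "snf_full_kernel",
    "snf_local_kernel",
    "snf_fuse",
    "fuse_feature_level",
]


@dataclass
class FusedAffinity:
    """Consensus affinity produced by SNF."""

    affinity: np.ndarray
    source_names: list
    snf_params: dict = field(default_factory=dict)
    patient_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.affinity, dtype=float)
        if np.abs(a - a.T).max(initial=0.0) > 1e-10:
            raise ValueError("fused affinity must be symmetric within 1e-10")
        if a.min(initial=0.0) < 0:
            raise ValueError("fused affinity must be nonnegative")
        self.affinity = (a + a.T) / 2
        if self.patient_ids is None:
            self.patient_ids = np.arange(a.shape[0]).astype(object)

    def to_psn(self, omics_name: str = "fused") -> PSN:
        """View as a PSN (affinity rescaled to [0, 1], zero diagonal)."""
        a = self.affinity.copy()
        np.fill_diagonal(a, 0.0)
        mx = a.max(initial=0.0)
        if mx > 1:
            a = a / mx
        return PSN(affinity=a, patient_ids=np.asarray(self.patient_ids),
                   omics_name=omics_name)


def _check_affinity(a: np.ndarray) -> np.ndarray:
    a = _as_affinity(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if np.abs(a - a.T).max(initial=0.0) > 1e-10:
        raise ValueError("affinity must be symmetric")
    if a.min(initial=0.0) < 0:
        raise ValueError("affinity must be nonnegative")
    return np.asarray(a, dtype=float)


def snf_full_kernel(a) -> np.ndarray:
    """Full SNF transition kernel.

    ``P[i, j] = a[i, j] / (2 * sum_{l != i} a[i, l])`` off the diagonal
    and ``P[i, i] = 1/2``, so every row sums to one while half the mass
    stays on the node itself.
    """
    a = _check_affinity(a)
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    dead = np.flatnonzero(row == 0)
    if dead.size:
        raise ValueError(f"patient index {dead[0]} has no off-diagonal affinity mass")
    p = off / (2.0 * row[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def snf_local_kernel(a, K: int) -> np.ndarray:
    """K-nearest-neighbor SNF kernel.

    Per row, the K largest off-diagonal entries (ties broken toward the
    lower patient index) are kept and renormalized to sum one; all other
    entries, including the diagonal, are zero.
    """
    a = _check_affinity(a)
    n = a.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must satisfy 1 <= K <= n-1, got {K}")
    s = np.zeros_like(a)
    for i in range(n):
        row = a[i].copy()
        row[i] = -np.inf
        order = np.argsort(-row, kind="stable")  # ties -> lower index first
        keep = order[:K]
        mass = a[i, keep].sum()
        if mass <= 0:
            # no positive neighbors: fall back to uniform over the kept set
            s[i, keep] = 1.0 / K
        else:
            s[i, keep] = a[i, keep] / mass
    return s


def snf_fuse(affinities, K: int | None = None, t: int = 20,
             source_names=None, patient_ids=None) -> FusedAffinity:
    """Similarity network fusion of two or more affinity matrices.

    Each source network's global kernel is updated as
    ``P_v <- S_v @ mean(P_u, u != v) @ S_v.T`` for ``t`` iterations
    (updates are simultaneous across sources and rows are renormalized
    after each iteration).  The fused network is the average of the
    final kernels, symmetrized, with the diagonal zeroed for downstream
    network-feature extraction.

    Parameters
    ----------
    affinities : list of symmetric nonnegative matrices (or PSNs)
    K : int, optional
        Neighborhood size of the local kernel; default ``min(20, n-1)``.
    t : int
        Number of cross-diffusion iterations (default 20).
    """
    mats = [_check_affinity(a) for a in affinities]
    if len(mats) < 2:
        raise ValueError("need at least 2 affinity matrices to fuse")
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all affinity matrices must have identical shape")
    if patient_ids is None:
        for src in affinities:
            if isinstance(src, PSN):
                patient_ids = src.patient_ids
                break
    for src in affinities:
        if isinstance(src, PSN) and patient_ids is not None:
            if list(src.patient_ids) != list(patient_ids):
                raise ValueError("patient ordering differs across sources")
    if K is None:
        K = min(20, n - 1)
    if t < 1:
        raise ValueError("t must be >= 1")

    P = [snf_full_kernel(m) for m in mats]
    S = [snf_local_kernel(m, K) for m in mats]
    m_src = len(mats)
    for _ in range(int(t)):
        new = []
        for v in range(m_src):
            others = [P[u] for u in range(m_src) if u != v]
            avg = sum(others) / len(others)
            p = S[v] @ avg @ S[v].T
            rows = p.sum(axis=1, keepdims=True)
            rows[rows == 0] = 1.0
            new.append(p / rows)
        P = new
    fused = sum(P) / m_src
    fused = (fused + fused.T) / 2
    np.fill_diagonal(fused, 0.0)
    if source_names is None:
        source_names = [
            src.omics_name if isinstance(src, PSN) else f"source{i}"
            for i, src in enumerate(affinities)
        ]
    return FusedAffinity(
        affinity=fused,
        source_names=list(source_names),
        snf_params={"K": int(K), "t": int(t)},
        patient_ids=None if patient_ids is None else np.asarray(patient_ids),
    )


def fuse_feature_level(tables) -> NetworkFeatureTable:
    """Feature-level fusion of per-network feature tables.

    The standard 13-column centrality blocks are averaged elementwise
    across tables; modularity blocks are concatenated in input order
    with source-tagged column metadata.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 feature tables to fuse")
    ids0 = list(tables[0].patient_ids)
    for tbl in tables[1:]:
        if list(tbl.patient_ids) != ids0:
            raise ValueError("patient ordering differs across feature tables")
    cents = []
    for tbl in tables:
        block = tbl.centrality_block
        if block.shape[1] != len(CENTRALITY_NAMES):
            raise ValueError(
                f"table {tbl.source!r} lacks the standard "
                f"{len(CENTRALITY_NAMES)}-column centrality block"
            )
        cents.append(block)
    mean_cent = np.mean(cents, axis=0)
    blocks = [mean_cent]
    meta = [f"centrality:{name}" for name in CENTRALITY_NAMES]
    for tbl in tables:
        mask = np.array(["modularity:" in m for m in tbl.column_meta])
        blocks.append(tbl.values[:, mask])
        meta.extend(
            f"{tbl.source}/{m}" for m, keep in zip(tbl.column_meta, mask) if keep
        )
    return NetworkFeatureTable(
        values=np.hstack(blocks),
        patient_ids=tables[0].patient_ids.copy(),
        column_meta=meta,
        source="+".join(t.source for t in tables),
    )
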