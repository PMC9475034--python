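"""Patient similarity networks with WGCNA-style soft thresholding.

A patient similarity network (PSN) is a complete weighted graph whose
nodes are patients and whose edge weights are pairwise similarities of
their omics profiles.  Similarity starts from the Pearson correlation of
patient profiles; correlations in [-1, 1] are rescaled to [0, 1] with
the signed WGCNA transform ``a = ((1 + r) / 2) ** beta``, and the power
``beta`` is chosen as the smallest integer for which the network's
connectivity distribution reaches a target truncated scale-free fit
(default R^2 >= 0.9), following weighted-correlation-network practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .omics_io import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PSN",
    "PSNConfig",
    "patient_correlation",
    "soft_threshold",
    "scale_free_fit_index",
    "select_soft_threshold",
    "build_psn",
]

DEFAULT_BETA_GRID = tuple(range(1, 21))


@dataclass
class PSN:
    """Soft-thresholded patient similarity network.

    affinity is symmetric, nonnegative, zero-diagonal, entries in [0, 1].
    """

    affinity: np.ndarray
    patient_ids: np.ndarray
    beta: int = 1
    fit_r2: float = float("nan")
    omics_name: str = "omics"

    def __post_init__(self) -> None:
        a = np.asarray(self.affinity, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("affinity must be square")
        if np.abs(a - a.T).max(initial=0.0) > 1e-10:
            raise ValueError("affinity must be symmetric within 1e-10")
        if np.abs(np.diag(a)).max(initial=0.0) > 0:
            raise ValueError("affinity diagonal must be zero")
        if a.min(initial=0.0) < 0 or a.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        self.affinity = (a + a.T) / 2
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        if len(self.patient_ids) != a.shape[0]:
            raise ValueError("patient_ids length must match affinity size")

    @property
    def n_patients(self) -> int:
        return self.affinity.shape[0]

    def to_graph(self) -> nx.Graph:
        """Weighted graph view; positive weights also carry length = 1/weight."""
        g = nx.Graph()
        ids = list(self.patient_ids)
        g.add_nodes_from(range(len(ids)))
        a = self.affinity
        n = a.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            w = a[i, j]
            if w > 0:
                g.add_edge(int(i), int(j), weight=float(w), length=1.0 / float(w))
        return g


@dataclass
class PSNConfig:
    target_r2: float = 0.9
    beta_grid: tuple = DEFAULT_BETA_GRID
    n_bins: int = 10


def patient_correlation(x: OmicsMatrix) -> np.ndarray:
    """Pearson correlation between all pairs of patient profiles.

    Raises if any patient has a constant (zero-variance) profile, naming
    the patient.
    """
    v = x.values
    if x.n_features < 2:
        raise ValueError("need at least 2 features to correlate patients")
    sd = v.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"patient {x.patient_ids[bad[0]]!r} has a zero-variance profile"
        )
    r = np.corrcoef(v)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def soft_threshold(corr: np.ndarray, beta: int) -> np.ndarray:
    """Signed WGCNA rescaling ``a = ((1 + r) / 2) ** beta``, zero diagonal.

    The signed form maps r = -1 to affinity 0 and r = +1 to 1, so
    anti-correlated patients are maximally dissimilar rather than
    maximally similar.
    """
    beta = int(beta)
    if beta < 1:
        raise ValueError(f"beta must be an integer >= 1, got {beta}")
    corr = np.asarray(corr, dtype=float)
    a = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return (a + a.T) / 2


def _as_affinity(obj) -> np.ndarray:
    if isinstance(obj, PSN):
        return obj.affinity
    if isinstance(obj, nx.Graph):
        return nx.to_numpy_array(obj, weight="weight")
    return np.asarray(obj, dtype=float)


def scale_free_fit_index(affinity, n_bins: int = 10) -> float:
    """Truncated scale-free topology fit index of a weighted network.

    Node connectivities ``k_u = sum_v a_uv`` are histogrammed into
    ``n_bins`` equal-width bins; the log10 bin frequency is regressed on
    log10 of the mean bin connectivity plus a truncation term (the mean
    connectivity itself).  The R^2 of that fit is returned when the
    log-connectivity slope is negative, 0 otherwise.  Degenerate inputs
    (all connectivities equal, fewer than 3 occupied bins) return 0.
    """
    a = _as_affinity(affinity)
    k = a.sum(axis=1)
    if np.ptp(k) == 0:
        return 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    occupied = counts > 0
    if occupied.sum() < 3:
        return 0.0
    # mean connectivity per occupied bin
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    kmean = np.array([k[which == b].mean() for b in np.flatnonzero(occupied)])
    freq = counts[occupied] / counts.sum()
    if (kmean <= 0).any():
        return 0.0
    logk = np.log10(kmean)
    logp = np.log10(freq)
    X = np.column_stack([np.ones_like(logk), logk, kmean])
    coef, *_ = np.linalg.lstsq(X, logp, rcond=None)
    resid = logp - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((logp - logp.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - ss_res / ss_tot
    slope_logk = coef[1]
    if slope_logk >= 0:
        return 0.0
    return float(max(0.0, min(1.0, r2)))


def select_soft_threshold(
    corr: np.ndarray,
    target_r2: float = 0.9,
    beta_grid=DEFAULT_BETA_GRID,
    n_bins: int = 10,
):
    """Pick the smallest power whose network meets the scale-free target.

    Scans ``beta_grid`` in ascending order and returns ``(beta, fit_r2)``
    for the first power whose soft-thresholded affinity reaches
    ``target_r2``.  If none qualifies, the power maximizing the fit
    index is returned and a warning is logged.
    """
    grid = [int(b) for b in beta_grid]
    if not grid or any(b2 < b1 for b1, b2 in zip(grid, grid[1:])):
        raise ValueError("beta_grid must be a nonempty ascending sequence")
    if not 0 < target_r2 <= 1:
        raise ValueError(f"target_r2 must be in (0, 1], got {target_r2}")
    fits = []
    for beta in grid:
        r2 = scale_free_fit_index(soft_threshold(corr, beta), n_bins=n_bins)
        fits.append(r2)
        if r2 >= target_r2:
            return beta, r2
    best = int(np.argmax(fits))
    logger.warning(
        "no power in %s reached scale-free fit %.2f; falling back to beta=%d "
        "(fit %.3f)",
        grid,
        target_r2,
        grid[best],
        fits[best],
    )
    return grid[best], fits[best]


def build_psn(x: OmicsMatrix, config: PSNConfig | None = None) -> PSN:
    """Correlate patients, pick the soft-threshold power, build the PSN."""
    config = config or PSNConfig()
    r = patient_correlation(x)
    beta, fit_r2 = select_soft_threshold(
        r, target_r2=config.target_r2, beta_grid=config.beta_grid, n_bins=config.n_bins
    )
    a = soft_threshold(r, beta)
    return PSN(
        affinity=a,
        patient_ids=x.patient_ids.copy(),
        beta=beta,
        fit_r2=fit_r2,
        omics_name=x.omics_name,
    )
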