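"""Synthetic multi-omics cohorts and benchmark graphs with known structure.

Real multi-omics studies of this kind pair either two technologies
measuring the same molecular layer (e.g. microarray and RNA-seq gene
expression — a *homogeneous* pair) or two distinct layers (e.g.
expression and DNA methylation — a *heterogeneous* pair).  The generator
emulates both situations with Gaussian features: a subset of
"informative" features carries a class-dependent mean shift, everything
else is noise.  In homogeneous mode the informative block is one shared
latent signal re-measured with independent noise per omics; in
heterogeneous mode each omics draws its own independent informative set.

Ground-truth informative indices and exact label counts are returned so
downstream feature selection and classification can be scored against
the truth.  All randomness flows from the spec's seed; the same spec
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .omics_io import OmicsMatrix

__all__ = [
    "SyntheticSpec",
    "MultiOmicsSample",
    "generate_multiomics",
    "generate_preferential_attachment_graph",
    "planted_block_affinity",
    "two_cluster_omics",
    "write_omics_tsv",
    "write_labels_tsv",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic multi-omics cohort.

    Parameters
    ----------
    n_patients : int
    dims : list of int
        Feature count of each omics matrix.
    n_informative : int or list of int
        Number of class-informative features per omics.  In homogeneous
        mode all omics must share one count (the shared latent signal).
    effect_size : float
        Standardized mean shift (in units of ``noise_sd``) added to
        class-1 patients on informative features.
    imbalance : float in (0.5, 1)
        Fraction of patients in the majority class (label 0, "alive");
        determines exact label counts by rounding.
    mode : {"homogeneous", "heterogeneous"}
    noise_sd : float
        Standard deviation of the Gaussian feature noise.
    seed : int
        Required; there is no hidden global RNG.
    """

    n_patients: int
    dims: list
    n_informative: object = 10
    effect_size: float = 1.0
    imbalance: float = 0.77
    mode: str = "heterogeneous"
    noise_sd: float = 1.0
    seed: int = 0

    def informative_per_omics(self) -> list:
        if np.isscalar(self.n_informative):
            return [int(self.n_informative)] * len(self.dims)
        return [int(v) for v in self.n_informative]

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients: must be at least 2")
        if not self.dims or any(int(d) < 1 for d in self.dims):
            raise ValueError("dims: must be a non-empty list of positive counts")
        n_inf = self.informative_per_omics()
        if len(n_inf) != len(self.dims):
            raise ValueError("n_informative: length must match dims")
        for k, d in zip(n_inf, self.dims):
            if not 0 <= k <= int(d):
                raise ValueError("n_informative: must satisfy 0 <= n_informative <= dim")
        if not 0.5 < self.imbalance < 1:
            raise ValueError("imbalance: must lie in (0.5, 1)")
        if self.mode not in ("homogeneous", "heterogeneous"):
            raise ValueError("mode: must be 'homogeneous' or 'heterogeneous'")
        if self.mode == "homogeneous" and len(set(n_inf)) > 1:
            raise ValueError(
                "n_informative: homogeneous mode shares one latent signal, "
                "so all omics need the same informative count"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd: must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size: must be nonnegative")
        if self.seed is None:
            raise ValueError("seed: required")


@dataclass
class MultiOmicsSample:
    """A generated cohort: matrices, labels and ground truth."""

    matrices: list
    labels: np.ndarray
    informative: list  # per-omics arrays of informative feature indices
    patient_ids: np.ndarray

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.patient_ids))


def _make_labels(n: int, imbalance: float, rng: np.random.Generator) -> np.ndarray:
    n_major = int(round(imbalance * n))
    y = np.zeros(n, dtype=int)
    y[n_major:] = 1
    rng.shuffle(y)
    return y


def generate_multiomics(spec: SyntheticSpec) -> MultiOmicsSample:
    """Generate one synthetic multi-omics cohort.

    Returns a :class:`MultiOmicsSample` whose matrices share patient IDs
    in identical order.  Informative features have the class-1 mean
    shifted by ``effect_size * noise_sd``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    y = _make_labels(n, spec.imbalance, rng)
    patient_ids = np.array([f"P{i:04d}" for i in range(n)], dtype=object)
    n_inf = spec.informative_per_omics()
    shift = spec.effect_size * spec.noise_sd

    matrices, informative = [], []
    if spec.mode == "homogeneous":
        k = n_inf[0]
        # one latent transcriptome-like signal, re-measured per omics
        latent = rng.normal(0.0, spec.noise_sd, size=(n, k))
        latent[y == 1] += shift
        for m, d in enumerate(spec.dims):
            idx = np.sort(rng.choice(int(d), size=k, replace=False))
            vals = rng.normal(0.0, spec.noise_sd, size=(n, int(d)))
            meas_noise = rng.normal(0.0, spec.noise_sd, size=(n, k))
            vals[:, idx] = latent + meas_noise
            matrices.append(
                _as_matrix(vals, patient_ids, int(d), f"omics{m}")
            )
            informative.append(idx)
    else:
        for m, d in enumerate(spec.dims):
            k = n_inf[m]
            idx = np.sort(rng.choice(int(d), size=k, replace=False))
            vals = rng.normal(0.0, spec.noise_sd, size=(n, int(d)))
            vals[np.ix_(y == 1, idx)] += shift
            matrices.append(
                _as_matrix(vals, patient_ids, int(d), f"omics{m}")
            )
            informative.append(idx)
    return MultiOmicsSample(
        matrices=matrices, labels=y, informative=informative, patient_ids=patient_ids
    )


def _as_matrix(vals, patient_ids, d, name) -> OmicsMatrix:
    feature_ids = np.array([f"{name}_f{i}" for i in range(d)], dtype=object)
    return OmicsMatrix(
        values=vals, patient_ids=patient_ids, feature_ids=feature_ids, omics_name=name
    )


def generate_preferential_attachment_graph(
    n: int, m_edges: int, seed: int
) -> nx.Graph:
    """Barabasi-Albert graph with unit edge weights.

    Grown by preferential attachment, so the degree distribution follows
    an (asymptotic) power law — the canonical positive control for
    scale-free topology fitting.
    """
    if not 1 <= m_edges < n:
        raise ValueError(f"m_edges must satisfy 1 <= m_edges < n, got {m_edges}")
    g = nx.barabasi_albert_graph(n, m_edges, seed=int(seed))
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def planted_block_affinity(
    n: int,
    k: int,
    within: float = 0.9,
    between: float = 0.1,
    noise: float = 0.02,
    seed: int = 0,
):
    """Symmetric affinity matrix with k planted blocks.

    Entries are ``within`` inside a block and ``between`` across blocks,
    plus small symmetric uniform noise; the diagonal is zero.  Returns
    ``(affinity, labels)`` with balanced block sizes.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    same = labels[:, None] == labels[None, :]
    a = np.where(same, within, between).astype(float)
    eps = rng.uniform(-noise, noise, size=(n, n))
    a = a + (eps + eps.T) / 2
    a = np.clip(a, 0.0, 1.0)
    np.fill_diagonal(a, 0.0)
    return a, labels


def two_cluster_omics(
    n: int,
    d: int,
    separation: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Omics matrix whose patients fall into two correlation clusters.

    Each cluster has its own random mean profile (scaled by
    ``separation``); patients are profile + Gaussian noise, so
    within-cluster patient correlations exceed between-cluster ones.
    Returns ``(OmicsMatrix, cluster_labels)``.
    """
    rng = np.random.default_rng(seed)
    labels = (np.arange(n) % 2).astype(int)
    profiles = rng.normal(0.0, separation * noise_sd, size=(2, d))
    vals = profiles[labels] + rng.normal(0.0, noise_sd, size=(n, d))
    ids = np.array([f"P{i:04d}" for i in range(n)], dtype=object)
    x = OmicsMatrix(
        values=vals,
        patient_ids=ids,
        feature_ids=np.array([f"f{i}" for i in range(d)], dtype=object),
        omics_name="two_cluster",
    )
    return x, labels


def correlated_block_omics(
    n: int = 120,
    d: int = 300,
    block_sizes=(40, 25, 18, 12, 9, 7, 5, 4),
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Omics matrix with correlated patient blocks of uneven size.

    Each block shares a random mean profile and each patient has an
    individual signal strength, so the resulting patient-correlation
    network has heterogeneous connectivity — the regime in which a
    soft-threshold power can make the network scale-free.  Returns
    ``(OmicsMatrix, block_labels)``.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)[:n]
    if len(labels) < n:
        raise ValueError("block_sizes must sum to at least n")
    profiles = rng.normal(0.0, noise_sd, size=(len(block_sizes), d))
    strength = rng.uniform(0.4, 1.6, size=n)
    vals = strength[:, None] * profiles[labels] + rng.normal(0, noise_sd, size=(n, d))
    ids = np.array([f"P{i:04d}" for i in range(n)], dtype=object)
    x = OmicsMatrix(
        values=vals,
        patient_ids=ids,
        feature_ids=np.array([f"f{i}" for i in range(d)], dtype=object),
        omics_name="correlated_blocks",
    )
    return x, labels


def write_omics_tsv(x: OmicsMatrix, path) -> None:
    """Write patients-as-rows TSV: first column patient ID, header = features."""
    df = x.to_frame()
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t")


def write_labels_tsv(labels, patient_ids, path) -> None:
    pd.DataFrame({"patient_id": list(patient_ids), "label": np.asarray(labels, int)}).to_csv(
        path, sep="\t", index=False
    )
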