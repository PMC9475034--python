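"""Loading, cleaning and univariate prefiltering of omics matrices.

An omics matrix holds one data type (expression, methylation, ...) as a
patients x features table of real values.  Loading enforces the cleaning
rules used throughout the pipeline: features with missing values are
dropped, duplicate patient or feature identifiers keep the first
occurrence, and the result is always oriented patients-as-rows.

The prefilter is the standard univariate screen for case/control omics
data: a two-sample Wilcoxon rank-sum (Mann-Whitney U) test per feature,
Benjamini-Hochberg correction across all features, and a hard threshold
on the adjusted p-value (default 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "load_omics_matrix",
    "load_labels",
    "filter_features_ranktest",
]


class EmptyDataError(ValueError):
    """Raised when cleaning or filtering leaves no usable data."""


@dataclass
class OmicsMatrix:
    """One omics type's measurements for a patient cohort.

    Parameters
    ----------
    values : ndarray of shape (n_patients, n_features)
        Real-valued measurements, no missing entries.
    patient_ids : ndarray of str
        Unique, ordered patient identifiers (rows).
    feature_ids : ndarray of str
        Unique, ordered feature identifiers (columns).
    omics_name : str
        Label for the omics type (e.g. ``"rnaseq"``).
    """

    values: np.ndarray
    patient_ids: np.ndarray
    feature_ids: np.ndarray
    omics_name: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D patients x features array")
        n, p = self.values.shape
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length does not match values rows")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match values columns")
        if len(set(self.patient_ids)) != n:
            raise ValueError("patient_ids must be unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("values must not contain missing entries")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.patient_ids), columns=list(self.feature_ids)
        )

    def select_features(self, mask_or_idx) -> "OmicsMatrix":
        """Return a copy restricted to the given feature columns (order kept)."""
        idx = np.asarray(mask_or_idx)
        return OmicsMatrix(
            values=self.values[:, idx],
            patient_ids=self.patient_ids.copy(),
            feature_ids=self.feature_ids[idx],
            omics_name=self.omics_name,
        )


def load_omics_matrix(
    path,
    orientation: str = "patients_rows",
    delimiter: str | None = None,
    omics_name: str | None = None,
) -> OmicsMatrix:
    """Read a delimited omics table and apply the cleaning rules.

    Parameters
    ----------
    path : str or Path
        Delimited text file; first column holds row identifiers, header
        holds column identifiers.
    orientation : {"patients_rows", "features_rows"}
        Whether rows of the file are patients or features.  The result
        is always patients x features.
    delimiter : str, optional
        Field delimiter; sniffed from the header line when omitted
        (tab if present, else comma).
    omics_name : str, optional
        Name attached to the matrix; defaults to the file stem.

    Notes
    -----
    Features containing any missing value are dropped; duplicate patient
    or feature identifiers keep the first occurrence.  Drop counts are
    logged at WARNING level.
    """
    if orientation not in ("patients_rows", "features_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = str(path)
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "features_rows":
        df = df.T

    # fail loudly on non-numeric cells, naming the offender
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.argmax(bad.to_numpy())]
                raise ValueError(
                    f"non-numeric value in {path}: row {row!r}, column {col!r}"
                )
            df[col] = coerced
    df = df.astype(float)

    n_dup_pat = int(df.index.duplicated().sum())
    if n_dup_pat:
        logger.warning("%s: dropped %d duplicate patient id(s)", path, n_dup_pat)
        df = df.loc[~df.index.duplicated(keep="first")]
    n_dup_feat = int(df.columns.duplicated().sum())
    if n_dup_feat:
        logger.warning("%s: dropped %d duplicate feature id(s)", path, n_dup_feat)
        df = df.loc[:, ~df.columns.duplicated(keep="first")]
    na_mask = df.isna().any(axis=0)
    if na_mask.any():
        logger.warning(
            "%s: dropped %d feature(s) with missing values", path, int(na_mask.sum())
        )
        df = df.loc[:, ~na_mask]

    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyDataError(f"{path}: no patients or features left after cleaning")
    name = omics_name
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(path))[0]
    return OmicsMatrix(
        values=df.to_numpy(float),
        patient_ids=df.index.astype(str).to_numpy(object),
        feature_ids=df.columns.astype(str).to_numpy(object),
        omics_name=name,
    )


def load_labels(path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (patient_id, label) table into a 0/1 Series."""
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 2:
        raise ValueError("labels file needs two columns: patient_id, label")
    s = pd.Series(
        df.iloc[:, 1].astype(int).to_numpy(), index=df.iloc[:, 0].astype(str)
    )
    if not set(s.unique()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return s


def _align_labels(x: OmicsMatrix, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        missing = [p for p in x.patient_ids if p not in labels.index]
        if missing:
            raise ValueError(f"labels missing for patients: {missing[:5]}")
        y = labels.loc[list(x.patient_ids)].to_numpy()
    else:
        y = np.asarray(labels)
        if len(y) != x.n_patients:
            raise ValueError("labels length does not match number of patients")
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def filter_features_ranktest(
    x: OmicsMatrix,
    labels,
    alpha: float = 0.001,
    return_pvalues: bool = False,
):
    """Univariate rank-test prefilter with Benjamini-Hochberg correction.

    Each feature is compared between the two outcome groups with a
    two-sample Mann-Whitney U test (normal approximation, tie
    correction).  P-values are BH-adjusted across all features and
    features with adjusted p < ``alpha`` are retained, in their original
    order.

    Parameters
    ----------
    x : OmicsMatrix
    labels : array-like or Series aligned to ``x.patient_ids``
    alpha : float in (0, 1]
        Threshold on the BH-adjusted p-value.
    return_pvalues : bool
        Also return the (raw, adjusted) p-value arrays.

    Returns
    -------
    OmicsMatrix restricted to the retained features, optionally followed
    by the raw and adjusted p-value arrays.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    y = _align_labels(x, labels)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both outcome classes must be non-empty")

    a = x.values[y == 0]
    b = x.values[y == 1]
    res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    # constant features yield a NaN/1.0 p depending on backend; force 1
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    keep = padj < alpha if alpha < 1.0 else padj <= 1.0
    if not keep.any():
        raise EmptyDataError(
            f"no features pass the BH-adjusted threshold alpha={alpha}; "
            "consider a larger alpha"
        )
    logger.info(
        "%s: retained %d / %d features at BH-adjusted p < %g",
        x.omics_name,
        int(keep.sum()),
        x.n_features,
        alpha,
    )
    out = x.select_features(np.flatnonzero(keep))
    if return_pvalues:
        return out, pvals, padj
    return out
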