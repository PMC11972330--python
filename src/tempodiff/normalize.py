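"""Counts -> log2(TPM+1) -> per-gene WT/KO profile pairs -> filtered, scaled.

The screen operates on one *profile pair* per gene: its expression series over
T shared time points in each of two conditions, on the log2(TPM+1) scale.
Replicates are aggregated per condition x timepoint (mean by default), genes
are filtered on the sample variance of the pooled 2T values, and each
retained pair is minmax-scaled with *joint* extrema so the WT/KO relationship
(which series is higher, and by how much relative to the gene's range) is
preserved:

    E' = (E - E_min) / (E_max - E_min),  E_min/E_max over the pooled 2T values.

Transformers follow the scikit-learn estimator API and compose in a Pipeline:
``TPMLogNormalizer`` (counts matrix -> expression matrix),
``ProfilePairBuilder`` (expression matrix -> ProfileSet),
``VarianceFilter`` and ``JointMinMaxScaler`` (ProfileSet -> ProfileSet).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._errors import DataError, DesignError

__all__ = [
    "ProfilePair",
    "ProfileSet",
    "counts_to_tpm",
    "log_transform",
    "build_profile_pairs",
    "filter_by_variance",
    "minmax_scale_pair",
    "TPMLogNormalizer",
    "ProfilePairBuilder",
    "VarianceFilter",
    "JointMinMaxScaler",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ProfilePair:
    """One gene's WT and KO expression series over T time points."""

    gene_id: str
    time_vector: np.ndarray
    wt: np.ndarray
    ko: np.ndarray
    variance14: float  # sample variance of the pooled 2T values (pre-scaling)
    scaled: bool = False
    e_min: float = np.nan  # joint extrema used for scaling
    e_max: float = np.nan
    degenerate: bool = False  # constant pair (e_max == e_min)


@dataclass(frozen=True)
class ProfileSet:
    """Vectorized collection of profile pairs (genes x T per condition)."""

    gene_ids: pd.Index
    time_vector: np.ndarray
    wt: np.ndarray  # (N, T)
    ko: np.ndarray  # (N, T)
    variance14: np.ndarray  # (N,)
    scaled: bool = False
    e_min: np.ndarray | None = None
    e_max: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __getitem__(self, gene_id: str) -> ProfilePair:
        i = self.gene_ids.get_loc(gene_id)
        return ProfilePair(
            gene_id=gene_id,
            time_vector=self.time_vector,
            wt=self.wt[i].copy(),
            ko=self.ko[i].copy(),
            variance14=float(self.variance14[i]),
            scaled=self.scaled,
            e_min=float(self.e_min[i]) if self.e_min is not None else np.nan,
            e_max=float(self.e_max[i]) if self.e_max is not None else np.nan,
            degenerate=bool(self.degenerate[i]) if self.degenerate is not None else False,
        )

    def subset(self, mask: np.ndarray) -> "ProfileSet":
        return replace(
            self,
            gene_ids=self.gene_ids[mask],
            wt=self.wt[mask],
            ko=self.ko[mask],
            variance14=self.variance14[mask],
            e_min=None if self.e_min is None else self.e_min[mask],
            e_max=None if self.e_max is None else self.e_max[mask],
            degenerate=None if self.degenerate is None else self.degenerate[mask],
        )

    def pairs(self) -> list[ProfilePair]:
        return [self[g] for g in self.gene_ids]


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------
def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: reads per kb of transcript per million mapped.

    tpm_g = (count_g / (len_g / 1000)) / sum_g'(count_g' / (len_g' / 1000)) * 1e6

    Every column of the result sums to 1e6.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise DataError(f"no gene length for {len(missing)} genes (first: {missing[0]!r})")
    lengths = gene_lengths.reindex(counts.index).to_numpy(dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        bad = counts.index[~(np.isfinite(lengths) & (lengths > 0))][0]
        raise DataError(f"non-positive or missing gene length for {bad!r}")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise DataError("negative counts encountered")
    rates = values / (lengths[:, None] / 1000.0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        sample = counts.columns[np.flatnonzero(zero)[0]]
        raise DataError(f"sample {sample!r} has all-zero counts; TPM undefined")
    tpm = rates / totals * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def log_transform(tpm: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise log2(tpm + 1); zero maps to zero."""
    values = tpm.to_numpy() if isinstance(tpm, pd.DataFrame) else np.asarray(tpm, dtype=float)
    if np.any(values < 0):
        raise DataError("log2(tpm+1) requires non-negative input")
    out = np.log2(values + 1.0)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    return out


def _aggregate(values: np.ndarray, how: str) -> np.ndarray:
    if how == "mean":
        return values.mean(axis=1)
    if how == "median":
        return np.median(values, axis=1)
    raise DataError(f"unknown aggregation {how!r}; expected 'mean' or 'median'")


def build_profile_pairs(
    expression: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    aggregation: str = "mean",
    conditions: tuple[str, str] = ("WT", "KO"),
) -> ProfileSet:
    """Collapse replicates into one series per gene x condition.

    Replicate expression values at each condition x timepoint are aggregated
    (arithmetic mean of log2(TPM+1) by default); ``variance14`` is the sample
    variance (denominator 2T-1) of the pooled 2T aggregated values.
    """
    cond_a, cond_b = conditions
    sheet = sample_sheet.set_index("sample_id")
    missing = [s for s in expression.columns if s not in sheet.index]
    if missing:
        raise DesignError(f"samples missing from sample sheet: {missing[:3]}")
    sheet = sheet.loc[list(expression.columns)]

    tp_a = set(sheet.loc[sheet["condition"] == cond_a, "timepoint"])
    tp_b = set(sheet.loc[sheet["condition"] == cond_b, "timepoint"])
    if tp_a != tp_b:
        only = sorted(tp_a.symmetric_difference(tp_b))
        raise DesignError(
            f"conditions do not cover the same timepoints; unmatched: {only}"
        )
    if not tp_a:
        raise DesignError(f"no samples for conditions {conditions}")
    time_vector = np.array(sorted(tp_a), dtype=float)

    series = {}
    for cond in conditions:
        cols = []
        for tp in time_vector:
            sel = (sheet["condition"] == cond) & (sheet["timepoint"] == tp)
            sample_cols = sheet.index[sel]
            cols.append(_aggregate(expression[sample_cols].to_numpy(dtype=float), aggregation))
        series[cond] = np.column_stack(cols)

    pooled = np.hstack([series[cond_a], series[cond_b]])
    variance14 = pooled.var(axis=1, ddof=1)
    return ProfileSet(
        gene_ids=pd.Index(expression.index, name="gene_id"),
        time_vector=time_vector,
        wt=series[cond_a],
        ko=series[cond_b],
        variance14=variance14,
    )


def filter_by_variance(profiles: ProfileSet, threshold: float = 0.1) -> ProfileSet:
    """Retain pairs whose pooled-2T sample variance strictly exceeds threshold."""
    return profiles.subset(profiles.variance14 > threshold)


def _scale_arrays(
    wt: np.ndarray, ko: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    pooled = np.hstack([wt, ko])
    e_min = pooled.min(axis=1)
    e_max = pooled.max(axis=1)
    span = e_max - e_min
    degenerate = span == 0
    safe = np.where(degenerate, 1.0, span)
    wt_s = (wt - e_min[:, None]) / safe[:, None]
    ko_s = (ko - e_min[:, None]) / safe[:, None]
    wt_s[degenerate] = 0.0
    ko_s[degenerate] = 0.0
    return wt_s, ko_s, e_min, e_max, degenerate


def minmax_scale_pair(pair: ProfilePair) -> ProfilePair:
    """Jointly minmax-scale one pair so the pooled 2T values span [0, 1].

    A constant pair (e_max == e_min) is mapped to all zeros and flagged
    ``degenerate`` rather than raising.
    """
    wt_s, ko_s, e_min, e_max, degenerate = _scale_arrays(
        pair.wt[None, :], pair.ko[None, :]
    )
    return replace(
        pair,
        wt=wt_s[0],
        ko=ko_s[0],
        scaled=True,
        e_min=float(e_min[0]),
        e_max=float(e_max[0]),
        degenerate=bool(degenerate[0]),
    )


def minmax_scale_set(profiles: ProfileSet) -> ProfileSet:
    """Vectorized joint minmax scaling of every pair in the set."""
    wt_s, ko_s, e_min, e_max, degenerate = _scale_arrays(profiles.wt, profiles.ko)
    return replace(
        profiles, wt=wt_s, ko=ko_s, scaled=True, e_min=e_min, e_max=e_max, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------
class TPMLogNormalizer(TransformerMixin, BaseEstimator):
    """Transform a raw count matrix into log2(TPM+1) expression values.

    Parameters
    ----------
    gene_lengths : pandas.Series
        Transcript lengths in bp, indexed by gene_id; must cover every gene
        in the matrices passed to :meth:`transform`.
    """

    def __init__(self, gene_lengths: pd.Series | None = None):
        self.gene_lengths = gene_lengths

    def fit(self, X: pd.DataFrame, y=None):
        if self.gene_lengths is None:
            raise DataError("TPMLogNormalizer requires gene_lengths")
        counts_to_tpm(X.iloc[:, :1], self.gene_lengths)  # validates coverage
        self.n_genes_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "n_genes_in_")
        return log_transform(counts_to_tpm(X, self.gene_lengths))


class ProfilePairBuilder(TransformerMixin, BaseEstimator):
    """Build per-gene WT/KO profile pairs from an expression matrix."""

    def __init__(
        self,
        sample_sheet: pd.DataFrame | None = None,
        aggregation: str = "mean",
        conditions: tuple[str, str] = ("WT", "KO"),
    ):
        self.sample_sheet = sample_sheet
        self.aggregation = aggregation
        self.conditions = conditions

    def fit(self, X: pd.DataFrame, y=None):
        if self.sample_sheet is None:
            raise DesignError("ProfilePairBuilder requires a sample sheet")
        self.n_samples_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> ProfileSet:
        check_is_fitted(self, "n_samples_in_")
        return build_profile_pairs(
            X, self.sample_sheet, aggregation=self.aggregation, conditions=self.conditions
        )


class VarianceFilter(TransformerMixin, BaseEstimator):
    """Drop profile pairs with pooled-2T sample variance <= threshold.

    Analogue of ``sklearn.feature_selection.VarianceThreshold``, but the
    variance is over each gene's pooled WT+KO aggregated series and the
    inequality is strict.
    """

    def __init__(self, threshold: float = 0.1):
        self.threshold = threshold

    def fit(self, X: ProfileSet, y=None):
        self.variances_ = X.variance14.copy()
        self.support_ = X.variance14 > self.threshold
        self.n_retained_ = int(self.support_.sum())
        return self

    def transform(self, X: ProfileSet) -> ProfileSet:
        check_is_fitted(self, "support_")
        return X.subset(X.variance14 > self.threshold)


class JointMinMaxScaler(TransformerMixin, BaseEstimator):
    """Scale each pair's pooled values onto [0, 1] with shared extrema."""

    def fit(self, X: ProfileSet, y=None):
        pooled = np.hstack([X.wt, X.ko])
        self.data_min_ = pooled.min(axis=1)
        self.data_max_ = pooled.max(axis=1)
        self.n_degenerate_ = int((self.data_max_ == self.data_min_).sum())
        return self

    def transform(self, X: ProfileSet) -> ProfileSet:
        check_is_fitted(self, "data_min_")
        return minmax_scale_set(X)
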