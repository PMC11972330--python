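"""Empirical tail-probability screen and cross-metric consensus.

For each dissimilarity metric, a gene's p-value is the self-inclusive
empirical tail probability of its WT/KO distance among all screened genes:

    p(g) = #{g' : d(g') >= d(g)} / N

so the gene with the single largest distance gets p = 1/N, ties share one p,
and selecting p <= alpha with tie-free distances returns exactly
floor(alpha * N) genes — the "alpha highest distances" rule. Genes are then
ranked by the number of metrics calling them significant (consensus count),
with mean p across metrics and gene id as deterministic tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._errors import ConfigError, DataError
from .metrics import METRIC_NAMES, MetricParams, compute_distance_table
from .normalize import ProfileSet

__all__ = [
    "ScreenResult",
    "empirical_pvalues",
    "select_significant",
    "consensus",
    "run_screen",
    "TemporalDivergenceScreen",
]

logger = logging.getLogger(__name__)


def empirical_pvalues(distances: np.ndarray | pd.Series) -> np.ndarray:
    """Self-inclusive empirical tail probabilities of one metric's distances.

    NaN inputs (metric inapplicable) yield NaN p-values and do not count
    toward N. All-identical values give p = 1 everywhere (nothing selectable).
    """
    values = np.asarray(distances, dtype=float)
    out = np.full(values.shape, np.nan)
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n < 2:
        raise DataError("empirical p-values require at least 2 finite distances")
    v = values[finite]
    # ascending min-rank r: #{d' >= d} = n - r + 1; ties share r, hence p
    r = rankdata(v, method="min")
    out[finite] = (n - r + 1) / n
    if np.all(v == v[0]):
        logger.warning("all %d distances identical; every empirical p = 1", n)
    return out


def select_significant(pvalues: np.ndarray | pd.Series, alpha: float = 0.01) -> np.ndarray:
    """Boolean mask of genes with empirical p <= alpha (NaN -> False)."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha={alpha} must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    with np.errstate(invalid="ignore"):
        return (p <= alpha) & np.isfinite(p)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the multi-metric screen.

    ``table`` holds only genes significant in at least one metric (the
    compiled selection), sorted by consensus count (descending), mean p
    (ascending), gene id. ``full`` holds every screened gene in input order.
    Columns: n_metrics_significant, mean_p, then d_/p_/sig_ triplets per
    metric.
    """

    table: pd.DataFrame
    full: pd.DataFrame
    alpha: float
    metrics: tuple[str, ...]

    @property
    def selected_gene_ids(self) -> pd.Index:
        return self.table.index

    def n_significant(self) -> pd.Series:
        return self.full["n_metrics_significant"]


def consensus(
    distances: pd.DataFrame,
    pvalues: pd.DataFrame,
    flags: pd.DataFrame,
    alpha: float,
) -> ScreenResult:
    """Assemble the consensus table from per-metric distances, p-values, flags."""
    metrics = tuple(distances.columns)
    n_sig = flags.sum(axis=1).astype(int)
    mean_p = pvalues.mean(axis=1, skipna=True)
    full = pd.DataFrame(
        {"n_metrics_significant": n_sig, "mean_p": mean_p}, index=distances.index
    )
    for m in metrics:
        full[f"d_{m}"] = distances[m]
        full[f"p_{m}"] = pvalues[m]
        full[f"sig_{m}"] = flags[m]
    selected = full[full["n_metrics_significant"] > 0].copy()
    # total order: consensus count desc, mean p asc, gene id asc
    selected["_gid"] = selected.index
    selected = selected.sort_values(
        by=["n_metrics_significant", "mean_p", "_gid"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_gid")
    return ScreenResult(table=selected, full=full, alpha=alpha, metrics=metrics)


def run_screen(
    profiles: ProfileSet,
    metrics: tuple[str, ...] | list[str] | None = None,
    params: MetricParams | None = None,
    alpha: float = 0.01,
) -> tuple[ScreenResult, pd.DataFrame]:
    """Full per-metric screen over a scaled, filtered ProfileSet.

    Computes every metric on every pair, converts each metric's column to
    empirical tail probabilities, selects p <= alpha per metric, and builds
    the consensus. Deterministic given inputs and params.
    """
    est = TemporalDivergenceScreen(metrics=metrics, alpha=alpha, metric_params=params)
    est.fit(profiles)
    return est.result_, est.distances_


class TemporalDivergenceScreen(BaseEstimator):
    """Multi-metric screen for condition-divergent expression trajectories.

    Fitting computes, for every profile pair, the requested dissimilarity
    metrics between the scaled WT and KO series; each metric's column is
    converted to empirical tail probabilities, genes with p <= ``alpha`` are
    flagged per metric, and the consensus table ranks genes by how many
    metrics flag them.

    Parameters
    ----------
    metrics : sequence of str or None
        Metric names to screen with; None means all 12 canonical metrics.
    alpha : float
        Empirical tail-probability cutoff (the "top alpha fraction" rule).
    metric_params : MetricParams or None
        Free parameters of the metric family.

    Attributes
    ----------
    distances_ : DataFrame, gene x metric dissimilarities
    pvalues_ : DataFrame, gene x metric empirical tail probabilities
    significant_ : DataFrame, gene x metric boolean flags
    n_significant_ : Series, consensus counts per gene
    result_ : ScreenResult, compiled sorted selection
    """

    def __init__(
        self,
        metrics: tuple[str, ...] | list[str] | None = None,
        alpha: float = 0.01,
        metric_params: MetricParams | None = None,
    ):
        self.metrics = metrics
        self.alpha = alpha
        self.metric_params = metric_params

    def fit(self, X: ProfileSet, y=None):
        if not isinstance(X, ProfileSet):
            raise DataError("TemporalDivergenceScreen.fit expects a ProfileSet")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha={self.alpha} must be in (0, 1)")
        names = tuple(self.metrics) if self.metrics is not None else METRIC_NAMES
        distances = compute_distance_table(X, metrics=names, params=self.metric_params)
        pvalues = pd.DataFrame(index=distances.index, columns=distances.columns, dtype=float)
        flags = pd.DataFrame(False, index=distances.index, columns=distances.columns)
        for m in names:
            pvalues[m] = empirical_pvalues(distances[m].to_numpy())
            flags[m] = select_significant(pvalues[m].to_numpy(), self.alpha)
            n_missing = int(distances[m].isna().sum())
            if n_missing:
                logger.info("metric %s: %d genes without a value (non-significant)", m, n_missing)
        self.distances_ = distances
        self.pvalues_ = pvalues
        self.significant_ = flags
        self.n_significant_ = flags.sum(axis=1).astype(int)
        self.result_ = consensus(distances, pvalues, flags, self.alpha)
        logger.info(
            "screened %d genes with %d metrics: %d significant in >=1 metric",
            len(X), len(names), len(self.result_.table),
        )
        return self

    def predict(self, X: ProfileSet | None = None) -> pd.Index:
        """Gene ids significant in at least one metric (the compiled table)."""
        check_is_fitted(self, "result_")
        return self.result_.selected_gene_ids
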