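"""End-to-end pipeline: matrix -> profiles -> filter -> scale -> screen.

Reports the gene-count funnel (input -> variance-filtered -> selected) so a
run on any dataset makes the attrition at each stage visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import RunConfig
from .normalize import (
    ProfileSet,
    build_profile_pairs,
    counts_to_tpm,
    filter_by_variance,
    log_transform,
    minmax_scale_set,
)
from .screen import ScreenResult, run_screen

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineResult:
    screen: ScreenResult
    distances: pd.DataFrame
    profiles: ProfileSet  # scaled, variance-filtered profiles that were screened
    funnel: dict

    @property
    def selected_gene_ids(self):
        return self.screen.selected_gene_ids


def run_pipeline(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    config: RunConfig,
    gene_lengths: pd.Series | None = None,
) -> PipelineResult:
    """Run the whole screen on a count (or expression) matrix.

    With ``config.expression_input`` False, ``matrix`` holds raw counts and
    ``gene_lengths`` is required for the log2(TPM+1) normalization; otherwise
    ``matrix`` is taken as already being on the log2(TPM+1) scale.
    """
    if config.expression_input:
        expression = matrix
    else:
        if gene_lengths is None:
            raise ValueError("gene_lengths required for count input")
        expression = log_transform(counts_to_tpm(matrix, gene_lengths))

    profiles = build_profile_pairs(
        expression,
        sample_sheet,
        aggregation=config.aggregation,
        conditions=config.conditions,
    )
    retained = filter_by_variance(profiles, config.variance_threshold)
    scaled = minmax_scale_set(retained)
    n_degenerate = int(scaled.degenerate.sum())
    if n_degenerate:
        logger.info("excluding %d degenerate (constant) pairs from screening", n_degenerate)
        scaled = scaled.subset(~scaled.degenerate)

    result, distances = run_screen(
        scaled, metrics=config.metrics, params=config.metric_params, alpha=config.alpha
    )
    funnel = {
        "n_genes_input": int(matrix.shape[0]),
        "n_profiles": len(profiles),
        "n_retained_variance": len(retained),
        "n_degenerate_excluded": n_degenerate,
        "n_screened": len(scaled),
        "n_selected_any_metric": int(len(result.table)),
    }
    logger.info(
        "funnel: %(n_genes_input)d genes -> %(n_retained_variance)d pass variance filter "
        "-> %(n_screened)d screened -> %(n_selected_any_metric)d selected in >=1 metric",
        funnel,
    )
    return PipelineResult(screen=result, distances=distances, profiles=scaled, funnel=funnel)
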