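"""End-to-end orchestration: matrices in, enrichment tables out."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    extract_target_vector,
    harmonize_samples,
    log2_transform,
)
from .gsea import EnrichmentResult, run_preranked
from .ranking import RankedGeneList, rank_by_dge, rank_by_gba, split_by_quantile

logger = logging.getLogger(__name__)


@dataclass
class TargetRun:
    target_id: str
    metric: str
    ranked: RankedGeneList
    result: EnrichmentResult


def rank_target(
    lnc: ExpressionMatrix,
    coding: ExpressionMatrix,
    target_id: str,
    metric: str = "gba",
    cor_method: str = "pearson",
    quantile: float = 0.25,
    barcode_fields: int = 4,
    assume_logged: bool = False,
    case_sensitive: bool = True,
) -> RankedGeneList:
    """Harmonize samples, log-transform, and rank coding genes for one target.

    ``metric`` is ``"dge"`` (quantile-split log2 fold change) or ``"gba"``
    (correlation across all samples). Raw matrices are put on log2(x+1)
    scale first unless ``assume_logged`` asserts they already are.
    """
    lnc, coding = harmonize_samples(lnc, coding, barcode_fields=barcode_fields)
    if not assume_logged:
        if not lnc.log_transformed:
            lnc = log2_transform(lnc)
        if not coding.log_transformed:
            coding = log2_transform(coding)
    target = extract_target_vector(lnc, target_id, case_sensitive=case_sensitive)
    if metric == "dge":
        high, low = split_by_quantile(target, q=quantile)
        return rank_by_dge(coding, high, low, target_id=target_id)
    if metric == "gba":
        return rank_by_gba(coding, target, method=cor_method, target_id=target_id)
    from .errors import ConfigError

    raise ConfigError(f"metric must be 'dge' or 'gba', got {metric!r}")


def analyze_target(
    lnc: ExpressionMatrix,
    coding: ExpressionMatrix,
    collection: GeneSetCollection,
    target_id: str,
    metric: str = "gba",
    cor_method: str = "pearson",
    quantile: float = 0.25,
    barcode_fields: int = 4,
    assume_logged: bool = False,
    min_size: int = 5,
    max_size: int = 500,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> TargetRun:
    """Full pipeline for one target lncRNA: ranking then pre-ranked GSEA."""
    ranked = rank_target(
        lnc, coding, target_id,
        metric=metric, cor_method=cor_method, quantile=quantile,
        barcode_fields=barcode_fields, assume_logged=assume_logged,
    )
    result = run_preranked(
        ranked, collection,
        min_size=min_size, max_size=max_size,
        weight_p=weight_p, n_perm=n_perm, seed=seed,
    )
    return TargetRun(target_id=target_id, metric=metric, ranked=ranked, result=result)
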