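"""Ranked coding-gene lists for a target lncRNA.

Two ranking metrics mirror the two ways of mimicking a knockdown contrast
in patient cohorts:

* **DGE** — split samples into high / low target-lncRNA expression groups
  at a quantile, rank genes by the difference of group means on log2(x+1)
  data (a log2 fold change).
* **GBA** (guilt by association) — rank genes by their Pearson or Spearman
  correlation with the target lncRNA across all samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

METRICS = ("log2fc", "pearson", "spearman")


@dataclass
class RankedGeneList:
    """Coding genes ordered by a signed ranking score, best first.

    Sorted by score strictly non-increasing; ties are broken by gene id
    (lexicographic ascending) so the ordering is deterministic.
    """

    genes: list[str]
    scores: np.ndarray
    metric: str
    target_id: str
    n_samples_used: int
    group_sizes: tuple[int, int] | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in ranked list")
        if not np.isfinite(self.scores).all():
            raise ValidationError("non-finite ranking scores")
        order = _sort_order(self.genes, self.scores)
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_rnk(self, path: str | Path) -> None:
        """Write as a 2-column TSV (the de-facto .rnk dialect)."""
        pd.DataFrame({"gene_id": self.genes, "score": self.scores}).to_csv(
            path, sep="\t", index=False, header=False, float_format="%.10g"
        )

    @classmethod
    def from_rnk(
        cls, path: str | Path, metric: str = "log2fc", target_id: str = ""
    ) -> "RankedGeneList":
        from .errors import InputIOError, MatrixParseError

        path = Path(path)
        if not path.exists():
            raise InputIOError(f"no such file: {path}")
        try:
            df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"])
            scores = df["score"].astype(float).to_numpy()
        except (ValueError, TypeError) as exc:
            raise MatrixParseError(f"{path}: malformed rank file ({exc})") from exc
        if df.shape[0] == 0:
            raise ValidationError(f"{path}: empty rank file")
        genes = df["gene_id"].astype(str).tolist()
        order = _sort_order(genes, scores)
        return cls(
            [genes[i] for i in order],
            scores[order],
            metric=metric,
            target_id=target_id,
            n_samples_used=0,
        )


def _sort_order(genes: list[str], scores: np.ndarray) -> np.ndarray:
    """Descending by score, ties broken by gene id ascending."""
    return np.lexsort((np.asarray(genes, dtype=str), -np.asarray(scores)))


def split_by_quantile(
    target: pd.Series, q: float = 0.25
) -> tuple[list[str], list[str]]:
    """Split samples into high / low groups at the q-th quantile of target abundance.

    Group sizes are exactly ``ceil(q * n)``: samples are ordered by
    (abundance, sample id) and the groups taken from the two ends, so ties
    are resolved deterministically by sample id and the groups are always
    disjoint.
    """
    if not (0 < q <= 0.5):
        raise ValidationError(f"quantile fraction must be in (0, 0.5], got {q}")
    n = len(target)
    if n < 4:
        raise ValidationError(f"need >= 4 samples to split, got {n}")
    k = math.ceil(q * n)
    if k < 2:
        raise ValidationError(
            f"group size ceil(q*n) = {k} < 2; increase q or add samples"
        )
    if 2 * k > n:
        raise ValidationError(
            f"groups of size {k} overlap on {n} samples; decrease q"
        )
    ids = np.asarray(target.index, dtype=str)
    values = target.to_numpy(dtype=float)
    order = np.lexsort((ids, values))  # ascending value, ties by sample id
    low = [str(s) for s in ids[order[:k]]]
    high = [str(s) for s in ids[order[-k:]]]
    return high, low


def rank_by_dge(
    coding: ExpressionMatrix,
    high_ids: list[str],
    low_ids: list[str],
    target_id: str = "",
) -> RankedGeneList:
    """Rank genes by log2 fold change between high and low lncRNA groups.

    The score is mean(log2 values over high) - mean(log2 values over low);
    the matrix must already be on log2(x+1) scale. Genes with any
    non-finite value are excluded (count logged).
    """
    if not coding.log_transformed:
        raise ValidationError("rank_by_dge requires a log2-transformed matrix")
    high_set, low_set = set(high_ids), set(low_ids)
    if high_set & low_set:
        raise ValidationError(
            f"high/low groups overlap: {sorted(high_set & low_set)[:5]}"
        )
    missing = (high_set | low_set) - set(coding.sample_ids)
    if missing:
        raise ValidationError(f"group sample ids not in matrix: {sorted(missing)[:5]}")
    sub_hi = coding.data.loc[:, list(high_ids)].to_numpy()
    sub_lo = coding.data.loc[:, list(low_ids)].to_numpy()
    finite = np.isfinite(sub_hi).all(axis=1) & np.isfinite(sub_lo).all(axis=1)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.info("rank_by_dge: excluded %d genes with non-finite values", n_excluded)
    scores = sub_hi[finite].mean(axis=1) - sub_lo[finite].mean(axis=1)
    genes = [g for g, ok in zip(coding.gene_ids, finite) if ok]
    order = _sort_order(genes, scores)
    return RankedGeneList(
        [genes[i] for i in order],
        scores[order],
        metric="log2fc",
        target_id=target_id,
        n_samples_used=len(high_ids) + len(low_ids),
        group_sizes=(len(high_ids), len(low_ids)),
        n_excluded=n_excluded,
    )


def rank_by_gba(
    coding: ExpressionMatrix,
    target: pd.Series,
    method: str = "pearson",
    target_id: str = "",
) -> RankedGeneList:
    """Rank genes by correlation with the target lncRNA across all samples.

    Spearman is computed as Pearson on midranks (average ranks for ties).
    Zero-variance genes are excluded with a logged count; a zero-variance
    target is a degenerate input.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"correlation method must be pearson or spearman, got {method!r}")
    if set(target.index) != set(coding.sample_ids):
        raise ValidationError("target vector and coding matrix index different samples")
    target = target.loc[coding.sample_ids]
    n = len(target)
    if n < 3:
        raise ValidationError(f"need >= 3 samples for correlation, got {n}")
    X = coding.values.astype(float)
    t = target.to_numpy(dtype=float)
    if method == "spearman":
        X = rankdata(X, axis=1)
        t = rankdata(t)
    t_c = t - t.mean()
    t_ss = float(t_c @ t_c)
    if t_ss == 0.0:
        raise DegenerateInputError("target lncRNA has zero variance across samples")
    X_c = X - X.mean(axis=1, keepdims=True)
    gene_ss = (X_c**2).sum(axis=1)
    keep = gene_ss > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("rank_by_gba: excluded %d zero-variance genes", n_excluded)
    scores = (X_c[keep] @ t_c) / np.sqrt(gene_ss[keep] * t_ss)
    genes = [g for g, ok in zip(coding.gene_ids, keep) if ok]
    order = _sort_order(genes, scores)
    return RankedGeneList(
        [genes[i] for i in order],
        scores[order],
        metric=method,
        target_id=target_id,
        n_samples_used=n,
        n_excluded=n_excluded,
    )
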