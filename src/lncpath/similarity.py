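"""Concordance between two ordered gene lists and between enrichment tables.

The similarity statistic is an exponentially weighted top+bottom overlap:
at each depth n = 1..n_top the number of genes shared by the first n
(and, symmetrically, the last n) entries of both lists is counted and
down-weighted by exp(-alpha * n). Because a reversed ranking is as
informative as a concordant one, a comparison scores both orientations
and keeps the larger ("same" vs "reversed" direction); the permutation
null applies the same max-over-orientations rule, so the test is
self-consistent. Per-comparison permutation p-values combine across
comparisons with Fisher's chi-square method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, ValidationError
from .gsea import EnrichmentResult

DEFAULT_N_TOP = 100


def default_alpha(n_top: int) -> float:
    """Decay such that the weight at depth n_top is ~0.01."""
    return math.log(100.0) / n_top


@dataclass
class SimilarityResult:
    score: float
    direction: str  # "same" or "reversed"
    p_perm: float
    alpha: float
    n_top: int
    n_perm: int
    seed: int

    def to_row(self) -> dict:
        return {
            "score": self.score,
            "direction": self.direction,
            "p_perm": self.p_perm,
            "alpha": self.alpha,
            "n_top": self.n_top,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass
class MetaResult:
    component_p: list[float]
    meta_p: float
    method: str = "fisher"


def _restrict_to_common(
    list_a: Sequence[str], list_b: Sequence[str]
) -> tuple[list[str], list[str]]:
    common = set(list_a) & set(list_b)
    if not common:
        raise ValidationError("the two gene lists share no genes")
    if len(set(list_a)) != len(list_a) or len(set(list_b)) != len(list_b):
        raise ValidationError("gene lists must not contain duplicates")
    return [g for g in list_a if g in common], [g for g in list_b if g in common]


def _check_params(alpha: float, n_top: int, n: int) -> None:
    if alpha <= 0:
        raise ConfigError(f"alpha must be positive, got {alpha}")
    if not (1 <= n_top <= n):
        raise ConfigError(f"n_top must be in [1, {n}], got {n_top}")


def _overlap_from_positions(pos: np.ndarray, alpha: float, n_top: int) -> float:
    """Weighted overlap given B-positions of A's genes in A order.

    The gene at A-position i (0-based) with B-position p first appears in
    both top-n windows at n = max(i, p) + 1, so the top overlap at depth n
    is a cumulative histogram of max(i, p); bottoms are the mirror image.
    O(N) per evaluation.
    """
    n = pos.size
    i = np.arange(n)
    m_top = np.maximum(i, pos)
    m_bot = np.maximum(n - 1 - i, n - 1 - pos)
    top_counts = np.cumsum(np.bincount(m_top, minlength=n))[:n_top]
    bot_counts = np.cumsum(np.bincount(m_bot, minlength=n))[:n_top]
    weights = np.exp(-alpha * np.arange(1, n_top + 1))
    return float(weights @ (top_counts + bot_counts))


def _positions(list_a: Sequence[str], list_b: Sequence[str]) -> np.ndarray:
    pos_b = {g: i for i, g in enumerate(list_b)}
    return np.fromiter((pos_b[g] for g in list_a), dtype=np.int64, count=len(list_a))


def weighted_overlap(
    list_a: Sequence[str],
    list_b: Sequence[str],
    alpha: float,
    n_top: int,
) -> float:
    """Exponentially weighted top+bottom overlap of two ordered gene lists.

    score = sum_{n=1..n_top} exp(-alpha*n) * (|topA_n ∩ topB_n| + |botA_n ∩ botB_n|).
    Both lists are restricted to their common gene universe first,
    preserving relative order.
    """
    a, b = _restrict_to_common(list_a, list_b)
    _check_params(alpha, n_top, len(a))
    return _overlap_from_positions(_positions(a, b), alpha, n_top)


def direction_and_score(
    list_a: Sequence[str],
    list_b: Sequence[str],
    alpha: float,
    n_top: int,
) -> tuple[str, float]:
    """Compare both orientations of list_b and keep the better one.

    Ties favor "same".
    """
    a, b = _restrict_to_common(list_a, list_b)
    _check_params(alpha, n_top, len(a))
    pos = _positions(a, b)
    s_same = _overlap_from_positions(pos, alpha, n_top)
    s_rev = _overlap_from_positions(len(a) - 1 - pos, alpha, n_top)
    if s_rev > s_same:
        return "reversed", s_rev
    return "same", s_same


def similarity_pvalue(
    list_a: Sequence[str],
    list_b: Sequence[str],
    alpha: float | None = None,
    n_top: int = DEFAULT_N_TOP,
    n_perm: int = 999,
    seed: int = 0,
) -> SimilarityResult:
    """Permutation test of ranked-list similarity.

    The observed statistic is the max-over-orientations weighted overlap;
    the null randomly permutes list_b ``n_perm`` times, each time taking
    the same per-permutation max, and
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")
    a, b = _restrict_to_common(list_a, list_b)
    n = len(a)
    n_top = min(n_top, n)
    if alpha is None:
        alpha = default_alpha(n_top)
    _check_params(alpha, n_top, n)
    pos = _positions(a, b)
    s_same = _overlap_from_positions(pos, alpha, n_top)
    s_rev = _overlap_from_positions(n - 1 - pos, alpha, n_top)
    direction = "reversed" if s_rev > s_same else "same"
    observed = max(s_same, s_rev)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        # a uniformly permuted list_b induces a uniformly random position map
        p = rng.permutation(n)
        null = max(
            _overlap_from_positions(p, alpha, n_top),
            _overlap_from_positions(n - 1 - p, alpha, n_top),
        )
        if null >= observed:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)
    return SimilarityResult(
        score=observed,
        direction=direction,
        p_perm=p_perm,
        alpha=alpha,
        n_top=n_top,
        n_perm=n_perm,
        seed=seed,
    )


def fisher_meta(p_values: Sequence[float]) -> MetaResult:
    """Fisher's chi-square combination of independent p-values.

    X = -2 sum(ln p_i) ~ chi2(2k) under the global null; meta_p is the
    upper tail at X.
    """
    ps = list(p_values)
    if len(ps) < 1:
        raise ValidationError("need at least one p-value")
    for p in ps:
        if not (0 < p <= 1):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    x = -2.0 * sum(math.log(p) for p in ps)
    meta_p = float(stats.chi2.sf(x, df=2 * len(ps)))
    return MetaResult(component_p=[float(p) for p in ps], meta_p=max(meta_p, np.nextafter(0, 1)))


def geneset_table_concordance(
    res_a: EnrichmentResult,
    res_b: EnrichmentResult,
    alpha: float | None = None,
    n_top: int | None = None,
) -> tuple[float, str, float]:
    """Concordance of two NES-ordered enrichment tables.

    Shared gene-set names are ordered by NES descending in each table and
    compared with the weighted-overlap statistic; additionally the
    Spearman rank correlation of the two NES vectors is reported.
    Returns ``(score, direction, spearman_rho)``.
    """
    a_nes = res_a.table["nes"].dropna()
    b_nes = res_b.table["nes"].dropna()
    shared = sorted(set(a_nes.index) & set(b_nes.index))
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared gene sets, got {len(shared)}")
    a_nes, b_nes = a_nes.loc[shared], b_nes.loc[shared]

    def _order(nes):
        df = nes.reset_index()
        df.columns = ["pathway", "nes"]
        df = df.sort_values(by=["nes", "pathway"], ascending=[False, True], kind="stable")
        return df["pathway"].tolist()

    if n_top is None:
        n_top = min(DEFAULT_N_TOP, len(shared))
    if alpha is None:
        alpha = default_alpha(n_top)
    direction, score = direction_and_score(_order(a_nes), _order(b_nes), alpha, n_top)
    rho = float(stats.spearmanr(a_nes.to_numpy(), b_nes.to_numpy()).statistic)
    return score, direction, rho
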