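"""Self-contained pre-ranked GSEA.

The enrichment statistic is the classic weighted Kolmogorov-Smirnov
running sum: walking the ranked gene list, the sum increments at gene-set
members ("hits") by ``|score|^p / N_R`` (``N_R`` = total hit weight) and
decrements at non-members by ``1 / (N - N_H)``; the enrichment score (ES)
is the running-sum value of maximal absolute deviation from zero. The
null distribution comes from gene-label permutation: random same-size
subsets of the ranked genes. NES normalizes the ES by the mean magnitude
of same-sign null values, nominal p-values use the +1 Monte-Carlo
correction, and FDR q-values are Benjamini-Hochberg across tested sets.

All of this is vectorized: a whole permutation block is scored with one
cumulative sum over an ``n_perm x N`` increment matrix, and null pools
are cached per set size within a run with per-size sub-seeds derived from
the master seed, so results do not depend on collection iteration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateInputError, ValidationError
from .io import GeneSetCollection
from .ranking import RankedGeneList

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-gene-set enrichment table plus run metadata.

    ``table`` is indexed by gene-set name with columns ``size``, ``es``,
    ``nes``, ``p_nominal``, ``q_fdr``, ``leading_edge`` (list of gene ids
    ordered by ranking position) and ``n_perm_effective``; rows are
    ordered by NES descending (undefined NES last). ``skipped`` maps the
    names of sets excluded before testing to the reason.
    """

    table: pd.DataFrame
    metadata: dict
    skipped: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["leading_edge"] = [",".join(le) for le in out["leading_edge"]]
        out.to_csv(path, sep="\t", index_label="pathway", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnrichmentResult":
        from .errors import InputIOError

        path = Path(path)
        if not path.exists():
            raise InputIOError(f"no such file: {path}")
        df = pd.read_csv(path, sep="\t", index_col="pathway")
        df["leading_edge"] = [
            le.split(",") if isinstance(le, str) and le else []
            for le in df["leading_edge"]
        ]
        return cls(df, metadata={"source": str(path)})


def _hit_mask(ranked: RankedGeneList, members: Iterable[str]) -> np.ndarray:
    members = set(members)
    return np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))


def _batch_running_stats(
    scores: np.ndarray, hits: np.ndarray, weight_p: float
) -> tuple[np.ndarray, np.ndarray]:
    """ES and peak index for each row of a boolean hit matrix.

    ``hits`` is (n_runs, N); every row must have at least one hit and at
    least one miss. Returns (es, peak_index) arrays of length n_runs.
    """
    n_runs, N = hits.shape
    n_hits = hits.sum(axis=1)
    w = np.abs(scores) ** weight_p
    hw = hits * w
    nr = hw.sum(axis=1)
    inc = np.where(hits, 0.0, -1.0 / (N - n_hits)[:, None])
    # if all hit weights are zero the hits increment uniformly
    safe_nr = np.where(nr > 0, nr, 1.0)
    hit_inc = np.where(nr[:, None] > 0, hw / safe_nr[:, None], hits / n_hits[:, None])
    inc = inc + np.where(hits, hit_inc, 0.0)
    rs = np.cumsum(inc, axis=1)
    peak = np.argmax(np.abs(rs), axis=1)  # first occurrence on ties
    es = rs[np.arange(n_runs), peak]
    return es, peak


def enrichment_score(
    ranked: RankedGeneList,
    members: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, int, np.ndarray]:
    """Weighted KS running-sum enrichment of *members* in the ranked list.

    Returns ``(es, peak_index, running_sum)``; ``peak_index`` is the
    0-based position of the first maximal absolute deviation.
    """
    if weight_p < 0:
        raise ConfigError(f"weight_p must be >= 0, got {weight_p}")
    hits = _hit_mask(ranked, members)
    N = len(ranked)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValidationError("gene set has empty intersection with the ranked list")
    if n_hits == N:
        raise DegenerateInputError(
            "gene set covers the whole ranked list; enrichment undefined"
        )
    w = np.abs(ranked.scores) ** weight_p
    hw = hits * w
    nr = hw.sum()
    if nr > 0:
        inc = np.where(hits, hw / nr, -1.0 / (N - n_hits))
    else:
        inc = np.where(hits, 1.0 / n_hits, -1.0 / (N - n_hits))
    rs = np.cumsum(inc)
    peak = int(np.argmax(np.abs(rs)))
    return float(rs[peak]), peak, rs


def leading_edge(
    ranked: RankedGeneList,
    members: Iterable[str],
    es: float,
    peak_index: int,
) -> list[str]:
    """Gene-set members driving the enrichment, ordered by ranking position.

    For a positive ES these are the members at positions <= peak_index
    (0-based); for a negative ES the members at positions >= peak_index.
    """
    N = len(ranked)
    if not (0 <= peak_index < N):
        raise ValidationError(f"peak_index {peak_index} outside [0, {N})")
    members = set(members)
    if es >= 0:
        span = range(0, peak_index + 1)
    else:
        span = range(peak_index, N)
    return [ranked.genes[i] for i in span if ranked.genes[i] in members]


def _sub_seed(seed: int, set_size: int) -> np.random.SeedSequence:
    """Deterministic per-set-size seed, independent of iteration order."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(set_size),))


def permutation_null(
    ranked: RankedGeneList,
    set_size: int,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Null ES values from uniform random same-size gene subsets.

    Reproducible given the seed; the same ``(ranked, set_size, weight_p,
    n_perm, seed)`` always yields the same vector.
    """
    N = len(ranked)
    if not (1 <= set_size < N):
        raise ConfigError(f"set_size must be in [1, {N}), got {set_size}")
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    # random subset of set_size indices per row via partial argsort of noise
    noise = rng.random((n_perm, N))
    idx = np.argpartition(noise, set_size - 1, axis=1)[:, :set_size]
    hits = np.zeros((n_perm, N), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    es, _ = _batch_running_stats(ranked.scores, hits, weight_p)
    return es


def _nes_p(es: float, null_es: np.ndarray) -> tuple[float, float, int]:
    """NES and nominal p against a same-size null pool.

    The NES divides the ES by the mean magnitude of same-sign null values
    (undefined — NaN, with p = 1 — when that pool is empty). The nominal p
    is the two-sided magnitude tail over the *full* pool,
    ``(1 + #{|null| >= |es|}) / (1 + n_perm)``: under the gene-label null
    the observed ES is one more draw from the pool, so this p is exactly
    uniform and its floor is 1/(n_perm+1) irrespective of how the nulls
    split by sign. Returns (nes, p_nominal, n_perm_effective).
    """
    n = int(null_es.size)
    if es == 0.0:
        return 0.0, 1.0, n
    pool = null_es[null_es > 0] if es > 0 else null_es[null_es < 0]
    if pool.size == 0:
        return float("nan"), 1.0, n
    nes = es / np.abs(pool).mean()
    p = (1 + int((np.abs(null_es) >= abs(es)).sum())) / (1 + n)
    return float(nes), float(p), n


def run_preranked(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Score every gene set in *collection* against the ranked list.

    Sets are filtered to ``min_size <= |set ∩ ranked genes| <= max_size``
    (skipped sets reported separately); the rest get ES, sign-stratified
    NES, Monte-Carlo nominal p (floor 1/(n_perm+1)), BH q across tested
    sets, and the leading-edge gene list.
    """
    if len(collection) == 0:
        raise ValidationError("empty gene-set collection")
    if min_size < 1 or max_size < min_size:
        raise ConfigError(f"bad size filter [{min_size}, {max_size}]")
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")

    universe = set(ranked.genes)
    N = len(ranked)
    tested: list[tuple[str, int, float, int]] = []  # name, size, es, peak
    skipped: dict[str, str] = {}
    for name in collection.names:
        size = len(collection.members(name) & universe)
        if size == 0:
            skipped[name] = "empty intersection with ranked list"
        elif size < min_size:
            skipped[name] = f"size {size} < min_size {min_size}"
        elif size > max_size:
            skipped[name] = f"size {size} > max_size {max_size}"
        elif size == N:
            skipped[name] = "covers the whole ranked list"
        else:
            es, peak, _ = enrichment_score(ranked, collection.members(name), weight_p)
            tested.append((name, size, es, peak))
    if not tested:
        raise ValidationError(
            f"no gene set passes the size filter [{min_size}, {max_size}]"
        )

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, size, es, peak in tested:
        if size not in null_cache:
            null_cache[size] = permutation_null(
                ranked, size, weight_p, n_perm, _sub_seed(seed, size)
            )
        nes, p, pool = _nes_p(es, null_cache[size])
        if np.isnan(nes):
            logger.info("set %s: empty same-sign null pool; NES undefined", name)
        le = leading_edge(ranked, collection.members(name), es, peak)
        rows.append(
            {
                "pathway": name,
                "size": size,
                "es": es,
                "nes": nes,
                "p_nominal": p,
                "leading_edge": le,
                "n_perm_effective": pool,
            }
        )
    table = pd.DataFrame(rows).set_index("pathway")
    table["q_fdr"] = multipletests(table["p_nominal"], method="fdr_bh")[1]
    table = table[
        ["size", "es", "nes", "p_nominal", "q_fdr", "leading_edge", "n_perm_effective"]
    ]
    # NES descending, undefined NES last, ties by name for determinism
    table = table.sort_values(
        by=["nes", "pathway"],
        ascending=[False, True],
        na_position="last",
        kind="stable",
    )
    metadata = {
        "metric": ranked.metric,
        "target_id": ranked.target_id,
        "weight_p": weight_p,
        "n_perm": n_perm,
        "seed": seed,
        "min_size": min_size,
        "max_size": max_size,
        "n_tested": len(tested),
        "n_skipped": len(skipped),
    }
    return EnrichmentResult(table, metadata, skipped)
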