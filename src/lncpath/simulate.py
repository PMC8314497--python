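"""Synthetic TCGA-like cohorts with planted lncRNA-pathway associations.

The generator emulates a tumor cohort profiled for one target lncRNA and
a few thousand coding genes. The signal model is linear in log2 space:
the target lncRNA's log2 abundance is Gaussian, and each *responsive*
gene's log2 abundance is

    baseline_g + effect_beta * lnc_log2 + Normal(0, noise_sd)

while null genes are baseline plus noise. This makes the expected
guilt-by-association correlation analytic,

    rho = beta * sigma_lnc / sqrt(beta^2 * sigma_lnc^2 + noise_sd^2),

and the expected fold change between high/low lncRNA groups equal to
beta times the group difference in mean lnc log2 abundance, so test
thresholds are derivable rather than guessed. A dropout fraction of
samples can have the lncRNA zeroed on the raw scale, emulating tumors
where the lncRNA is not expressed at all — the heterogeneity scenario in
which the quantile-split fold-change metric is preferable to
correlation. Matrices are emitted on the raw scale (2^x - 1, floored at
0) with ``log_transformed=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, GeneSetCollection, write_expression_matrix, write_gmt

TARGET_ID = "LNC_TARGET"


@dataclass(frozen=True)
class PlantedSet:
    name: str
    size: int
    effect_beta: float
    fraction_responsive: float = 1.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized TCGA-like cohort: 200 tumors, 2000
    coding genes, one planted 30-gene set whose members track the target
    lncRNA with unit effect in log2 space against noise_sd = 0.5, and 49
    null gene sets of 10-60 genes.
    """

    n_samples: int = 200
    n_genes: int = 2000
    planted_sets: tuple[PlantedSet, ...] = (PlantedSet("PLANTED_PATHWAY", 30, 1.0, 1.0),)
    n_null_sets: int = 49
    null_set_size_range: tuple[int, int] = (10, 60)
    noise_sd: float = 0.5
    lnc_mean: float = 4.0
    lnc_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    n_decoy_lncrnas: int = 9
    dropout_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 8:
            raise ConfigError(f"n_samples must be >= 8, got {self.n_samples}")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        total_planted = sum(s.size for s in self.planted_sets)
        if total_planted > self.n_genes:
            raise ConfigError(
                f"planted sets need {total_planted} genes but only {self.n_genes} exist"
            )
        for s in self.planted_sets:
            if not (0 <= s.fraction_responsive <= 1):
                raise ConfigError(f"fraction_responsive outside [0,1] in {s.name}")
            if s.size < 1:
                raise ConfigError(f"empty planted set {s.name}")
        if not (0 <= self.dropout_fraction <= 1):
            raise ConfigError("dropout_fraction outside [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        lo, hi = self.null_set_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad null_set_size_range {self.null_set_size_range}")
        if self.n_null_sets > 0 and hi > self.n_genes - total_planted:
            raise ConfigError("null sets larger than the pool of null genes")


@dataclass
class GroundTruth:
    """What was planted: per-set members and effects, per-gene responsive flags."""

    planted_members: dict[str, list[str]]
    effect_beta: dict[str, float]
    responsive: dict[str, bool]
    lnc_log2: pd.Series = field(repr=False, default=None)

    def responsive_genes(self) -> list[str]:
        return [g for g, r in self.responsive.items() if r]


def expected_gba_correlation(effect_beta: float, lnc_sd: float, noise_sd: float) -> float:
    """Closed-form Pearson correlation of a responsive gene with the target."""
    s = effect_beta * lnc_sd
    return s / np.sqrt(s * s + noise_sd * noise_sd)


def _raw(log2_values: np.ndarray) -> np.ndarray:
    return np.maximum(np.exp2(log2_values) - 1.0, 0.0)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GeneSetCollection, GroundTruth]:
    """Generate paired lncRNA / coding matrices, a GMT-style collection and truth.

    All randomness flows from ``config.seed``; the same config reproduces
    byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    sample_ids = [f"TCGA-SY-{i:04d}-01A" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]

    # target lncRNA: lognormal-scale abundance with optional hard dropout
    z = rng.normal(config.lnc_mean, config.lnc_sd, size=n)
    raw_lnc = _raw(z)
    n_drop = int(round(config.dropout_fraction * n))
    if n_drop:
        drop_idx = rng.choice(n, size=n_drop, replace=False)
        raw_lnc[drop_idx] = 0.0
    z_eff = np.log2(raw_lnc + 1.0)  # realized log2 abundance seen by coding genes

    # planted membership: disjoint random draw across planted sets
    order = rng.permutation(g)
    cursor = 0
    planted_members: dict[str, list[str]] = {}
    effect: dict[str, float] = {}
    responsive = {gi: False for gi in gene_ids}
    beta_per_gene = np.zeros(g)
    for ps in config.planted_sets:
        member_idx = order[cursor : cursor + ps.size]
        cursor += ps.size
        members = sorted(gene_ids[i] for i in member_idx)
        planted_members[ps.name] = members
        effect[ps.name] = ps.effect_beta
        n_resp = int(round(ps.fraction_responsive * ps.size))
        resp_idx = member_idx[:n_resp]
        for i in resp_idx:
            responsive[gene_ids[i]] = True
            beta_per_gene[i] = ps.effect_beta

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    noise = rng.normal(0.0, config.noise_sd, size=(g, n))
    log_coding = baselines[:, None] + beta_per_gene[:, None] * z_eff[None, :] + noise

    coding = ExpressionMatrix(
        pd.DataFrame(_raw(log_coding), index=gene_ids, columns=sample_ids),
        cohort="SYNTH",
        log_transformed=False,
    )

    # lncRNA matrix: the target plus independent decoy lncRNAs
    lnc_ids = [TARGET_ID] + [f"LNC_DECOY_{i:02d}" for i in range(config.n_decoy_lncrnas)]
    decoys = _raw(
        rng.normal(config.lnc_mean, config.lnc_sd, size=(config.n_decoy_lncrnas, n))
    )
    lnc = ExpressionMatrix(
        pd.DataFrame(
            np.vstack([raw_lnc[None, :], decoys]), index=lnc_ids, columns=sample_ids
        ),
        cohort="SYNTH",
        log_transformed=False,
    )

    # null sets drawn uniformly from genes outside every planted set
    planted_all = {m for members in planted_members.values() for m in members}
    null_pool = np.array([gi for gi in gene_ids if gi not in planted_all])
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for name, members in planted_members.items():
        sets[name] = ("planted", frozenset(members))
    lo, hi = config.null_set_size_range
    for j in range(config.n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(null_pool, size=size, replace=False)
        sets[f"NULL_SET_{j:03d}"] = ("null", frozenset(members.tolist()))
    collection = GeneSetCollection(sets, source_path="synthetic")

    truth = GroundTruth(
        planted_members=planted_members,
        effect_beta=effect,
        responsive=responsive,
        lnc_log2=pd.Series(z_eff, index=sample_ids, name=TARGET_ID),
    )
    return lnc, coding, collection, truth


def write_cohort(
    config: SyntheticConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Generate a cohort and write it in the dialects the readers consume.

    Emits ``lnc_matrix.tsv``, ``coding_matrix.tsv``, ``gene_sets.gmt``,
    ``truth_members.tsv`` and a plain-text ``manifest.txt`` recording the
    config. Returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lnc, coding, sets, truth = generate_cohort(config)
    paths = {
        "lnc": out_dir / "lnc_matrix.tsv",
        "coding": out_dir / "coding_matrix.tsv",
        "gmt": out_dir / "gene_sets.gmt",
        "truth": out_dir / "truth_members.tsv",
        "manifest": out_dir / "manifest.txt",
    }
    write_expression_matrix(lnc, paths["lnc"])
    write_expression_matrix(coding, paths["coding"])
    write_gmt(sets, paths["gmt"])
    rows = [
        {"set": name, "gene_id": gid, "effect_beta": truth.effect_beta[name],
         "responsive": truth.responsive[gid]}
        for name, members in truth.planted_members.items()
        for gid in members
    ]
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        fh.write(f"target_id={TARGET_ID}\n")
        for key in (
            "n_samples", "n_genes", "n_null_sets", "noise_sd", "lnc_mean",
            "lnc_sd", "baseline_mean", "baseline_sd", "dropout_fraction", "seed",
        ):
            fh.write(f"{key}={getattr(config, key)}\n")
        fh.write(
            "planted_sets="
            + ";".join(
                f"{s.name}:{s.size}:{s.effect_beta}:{s.fraction_responsive}"
                for s in config.planted_sets
            )
            + "\n"
        )
        fh.write(f"null_set_size_range={config.null_set_size_range[0]}-{config.null_set_size_range[1]}\n")
    return paths


@dataclass
class DegenerateFixture:
    """A tiny adversarial input paired with the handling the pipeline must show."""

    name: str
    expected: str
    payload: object


def degenerate_fixtures() -> dict[str, DegenerateFixture]:
    """Catalog of small degenerate inputs for edge-case testing.

    Each fixture documents, in ``expected``, the error or handling the
    pipeline must exhibit when fed the ``payload``.
    """
    samples = [f"TCGA-ZZ-{i:04d}-01A" for i in range(8)]
    flat = pd.DataFrame(
        {s: [5.0, float(i)] for i, s in enumerate(samples)},
        index=["FLAT_GENE", "VAR_GENE"],
    ).astype(float)
    fixtures = {
        "zero_variance_gene": DegenerateFixture(
            "zero_variance_gene",
            "rank_by_gba excludes the constant gene and logs the count",
            ExpressionMatrix(flat, cohort="FIX", log_transformed=True),
        ),
        "all_tied_lnc": DegenerateFixture(
            "all_tied_lnc",
            "split_by_quantile fills both groups in sample-id order, sizes ceil(q*n)",
            pd.Series([3.0] * 8, index=samples),
        ),
        "disjoint_samples": DegenerateFixture(
            "disjoint_samples",
            "harmonize_samples raises HarmonizationError",
            (
                ExpressionMatrix(
                    pd.DataFrame([[1.0, 2.0]], index=["L1"], columns=["TCGA-AA-0001-01A", "TCGA-AA-0002-01A"])
                ),
                ExpressionMatrix(
                    pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["TCGA-BB-0001-01A", "TCGA-BB-0002-01A"])
                ),
            ),
        ),
        "duplicate_gene_rows": DegenerateFixture(
            "duplicate_gene_rows",
            "read_expression_matrix keeps the duplicate row with the highest mean",
            "gene_id\tS1\tS2\nA\t4.0\t6.0\nA\t1.0\t3.0\nB\t2.0\t2.0\n",
        ),
        "short_gene_set_line": DegenerateFixture(
            "short_gene_set_line",
            "read_gmt raises GmtFormatError naming the line",
            "GOOD_SET\tdesc\tA\tB\nBAD_SET\tdesc-only-two-fields\n",
        ),
        "empty_member_list": DegenerateFixture(
            "empty_member_list",
            "read_gmt rejects a set whose member fields are all empty",
            "EMPTY_SET\tdesc\t\t\n",
        ),
    }
    return fixtures
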