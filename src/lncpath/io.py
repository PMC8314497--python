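"""Reading, validating and harmonizing expression matrices and gene-set collections.

Expression matrices are delimited text (TSV by default) with gene
identifiers in rows and sample identifiers in columns; a flag flips the
orientation on read. Gene sets use the GMT dialect: one set per line,
tab-separated, ``name<TAB>description<TAB>member1<TAB>member2...``.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    GmtFormatError,
    HarmonizationError,
    InputIOError,
    MatrixParseError,
    TargetNotFoundError,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance table.

    Values are non-negative FPKM/TPM-like abundances unless
    ``log_transformed`` is set, in which case they are on log2(x+1) scale.
    """

    data: pd.DataFrame
    cohort: str = ""
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if not self.log_transformed and (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r} on a matrix flagged as raw scale"
            )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[:, sample_ids])


@dataclass
class GeneSetCollection:
    """Named gene sets: mapping set name -> (description, frozenset of gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    source_path: str = ""

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    genes_in_rows: bool = True,
    cohort: str = "",
    log_transformed: bool = False,
) -> ExpressionMatrix:
    """Read a delimited genes x samples table.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean abundance (the standard rule for transcript-level duplicates).
    Any cell that does not parse as a finite number raises
    :class:`MatrixParseError` naming its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"no such file: {path}")
    # parse the header ourselves: pandas silently renames duplicate columns
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    col_ids = header[1:]
    try:
        body = pd.read_csv(
            path, sep=delimiter, header=None, skiprows=1,
            dtype=str, keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        body = pd.DataFrame()
    if body.shape[0] == 0 or not col_ids:
        raise ValidationError(f"empty matrix in {path}")
    if body.shape[1] != len(col_ids) + 1:
        raise MatrixParseError(
            f"{path}: header has {len(col_ids)} ids but rows have "
            f"{body.shape[1] - 1} value fields"
        )
    raw = body.iloc[:, 1:]
    raw.index = pd.Index(body.iloc[:, 0].astype(str))
    raw.columns = pd.Index(col_ids)
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(coerced.to_numpy(dtype=float)))
    if bad.size:
        r, c = bad[0]
        raise MatrixParseError(
            f"{path}: cell {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} is not a finite number"
        )
    # convert via float() semantics: correctly-rounded, so text round-trips
    numeric = pd.DataFrame(
        raw.to_numpy().astype(np.float64), index=raw.index.copy(), columns=raw.columns
    )
    numeric.index.name = None
    if not genes_in_rows:
        numeric = numeric.T
    if numeric.columns.has_duplicates:
        dups = numeric.columns[numeric.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups[:5]}")
    if numeric.index.has_duplicates:
        n_before = numeric.shape[0]
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        numeric = numeric.iloc[order]
        numeric = numeric[~numeric.index.duplicated(keep="first")]
        # restore original gene order after collapsing
        seen: dict[str, None] = {}
        for g in raw.index if genes_in_rows else raw.columns:
            seen.setdefault(g, None)
        numeric = numeric.loc[list(seen)]
        logger.info(
            "collapsed %d duplicate gene rows (kept highest mean)",
            n_before - numeric.shape[0],
        )
    return ExpressionMatrix(numeric, cohort=cohort, log_transformed=log_transformed)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    m.data.to_csv(path, sep=delimiter, index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, tab-separated.

    Duplicate genes within one line are deduplicated; a line with fewer
    than three fields or a repeated set name is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputIOError(f"no such file: {path}")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [g for g in members if g]
            if not members:
                raise GmtFormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, frozenset(members))
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, source_path=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def truncate_barcode(sample_id: str, barcode_fields: int) -> str:
    """Keep the first *barcode_fields* dash-separated fields of a TCGA-style barcode."""
    return "-".join(sample_id.split("-")[:barcode_fields])


def harmonize_samples(
    lnc: ExpressionMatrix,
    coding: ExpressionMatrix,
    barcode_fields: int = 4,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Match samples of two matrices under TCGA-style barcode truncation.

    Sample ids are truncated to the first ``barcode_fields`` dash-separated
    fields (default 4, i.e. through the vial field of a TCGA barcode); both
    matrices are subset and column-ordered to the intersection of truncated
    ids, in the lncRNA matrix's order. Idempotent.
    """
    if barcode_fields < 1:
        raise ValidationError("barcode_fields must be >= 1")

    def _truncated(m: ExpressionMatrix) -> pd.DataFrame:
        trunc = [truncate_barcode(s, barcode_fields) for s in m.sample_ids]
        if len(set(trunc)) != len(trunc):
            counts: dict[str, int] = {}
            for t in trunc:
                counts[t] = counts.get(t, 0) + 1
            dups = [t for t, c in counts.items() if c > 1]
            raise ValidationError(
                f"barcode truncation to {barcode_fields} fields makes sample ids "
                f"collide: {dups[:5]}"
            )
        out = m.data.copy()
        out.columns = trunc
        return out

    a, b = _truncated(lnc), _truncated(coding)
    common = [s for s in a.columns if s in set(b.columns)]
    if not common:
        raise HarmonizationError(
            "no shared samples after barcode truncation; examples — "
            f"lnc side: {list(a.columns[:3])}, coding side: {list(b.columns[:3])}"
        )
    logger.info("harmonized to %d shared samples", len(common))
    lnc_out = replace(lnc, data=a.loc[:, common])
    coding_out = replace(coding, data=b.loc[:, common])
    return lnc_out, coding_out


def extract_target_vector(
    m: ExpressionMatrix, target_id: str, case_sensitive: bool = True
) -> pd.Series:
    """Return the abundance row of *target_id* as a sample-indexed vector.

    With ``case_sensitive=False`` an identifier differing only in case is
    accepted when the match is unique. An absent id raises
    :class:`TargetNotFoundError` listing up to 5 nearest identifiers.
    """
    if target_id in m.data.index:
        return m.data.loc[target_id].copy()
    if not case_sensitive:
        matches = [g for g in m.gene_ids if g.lower() == target_id.lower()]
        if len(matches) == 1:
            return m.data.loc[matches[0]].copy()
        if len(matches) > 1:
            raise ValidationError(
                f"target {target_id!r} matches several ids case-insensitively: {matches[:5]}"
            )
    near = difflib.get_close_matches(
        target_id.lower(), [g.lower() for g in m.gene_ids], n=5, cutoff=0.4
    )
    lower_map: dict[str, str] = {}
    for g in m.gene_ids:
        lower_map.setdefault(g.lower(), g)
    suggestions = [lower_map[g] for g in near]
    raise TargetNotFoundError(
        f"target {target_id!r} not found; nearest ids: {suggestions}"
    )


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return a copy of *m* with values replaced by log2(value + pseudocount)."""
    if m.log_transformed:
        raise ValidationError("matrix is already log2 transformed")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    data = np.log2(m.data + pseudocount)
    return ExpressionMatrix(data, cohort=m.cohort, log_transformed=True)
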