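"""Readers, writers and matrix preprocessing shared by all pipeline stages.

In-memory containers are thin dataclasses around pandas objects: an expression
matrix is genes x samples with a declared scale, an RPPA matrix is antibodies x
samples of level-3-like (already normalized) values, and a clinical table keys
age and BMI by sample id. All on-disk formats are plain TSV (gene-major, sample
columns) or standard GMT; no binary formats are used anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParseError

logger = logging.getLogger(__name__)

VALID_SCALES = ("counts", "log2", "intensity")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a declared measurement scale.

    ``scale`` is one of ``counts`` (raw non-negative integers from RNA-seq),
    ``log2`` (log2-normalized, e.g. log-CPM) or ``intensity`` (array-style
    pre-normalized intensities).
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        _check_matrix(self.data, kind="expression")
        if self.scale == "counts" and (self.data.to_numpy() < 0).any():
            raise ValueError("counts-scale matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class RPPAMatrix:
    """Antibody x samples matrix of normalized phospho/total protein levels.

    ``metadata`` optionally maps antibody id -> (protein, residue, modification).
    """

    data: pd.DataFrame
    metadata: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_matrix(self.data, kind="RPPA")

    @property
    def antibody_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates: age (years), BMI (kg/m2), optional group."""

    data: pd.DataFrame  # index: sample_id; columns: age, bmi[, group]

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dups}")
        for col in ("age", "bmi"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
            vals = pd.to_numeric(self.data[col], errors="raise")
            if (vals <= 0).any():
                bad = self.data.index[vals <= 0].tolist()
                raise ValueError(f"non-positive {col} for samples {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line): name, free-text description, members."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class ProbeAnnotation:
    """Mapping from array probe id to gene id (each probe maps to one gene)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("probe annotation is empty")


def _check_matrix(df: pd.DataFrame, kind: str) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {kind} matrix: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {kind} matrix: {dups[:5]}")
    values = df.to_numpy()
    if values.size and not np.isfinite(values.astype(float)).all():
        raise ValueError(f"{kind} matrix contains non-finite values")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample columns {dups} (line 1)")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        first_dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == first_dup)[0][-1]) + 2  # +1 header +1 one-based
        raise ParseError(
            f"{path}: duplicate row id {first_dup!r} (line {line}); collapse probes first"
        )
    try:
        df = df.astype(float)
    except ValueError as exc:
        for i, (_, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().any():
                raise ParseError(f"{path}: non-numeric cell on line {i}") from exc
        raise ParseError(f"{path}: non-numeric values") from exc
    if df.isna().to_numpy().any():
        raise ParseError(f"{path}: missing values are not permitted in a {kind} matrix")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def read_expression(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a gene-major TSV (first column gene id, remaining columns samples)."""
    return ExpressionMatrix(data=_read_matrix_tsv(path, "expression"), scale=scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write at full precision so a read round-trips bit-exactly."""
    _write_matrix_tsv(matrix.data, path, index_label="gene_id")


def read_rppa(path: str | Path) -> RPPAMatrix:
    """Read an antibody-major TSV of level-3-like normalized RPPA values."""
    return RPPAMatrix(data=_read_matrix_tsv(path, "RPPA"))


def write_rppa(matrix: RPPAMatrix, path: str | Path) -> None:
    _write_matrix_tsv(matrix.data, path, index_label="antibody_id")


def _write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(Path(path), sep="\t", index_label=index_label, float_format="%.17g")


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: clinical table must have a sample_id column")
    df = df.set_index("sample_id")
    df.index.name = None
    return ClinicalTable(data=df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(Path(path), sep="\t", index_label="sample_id", float_format="%.17g")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a standard GMT file: name TAB description TAB member ids.

    Duplicate members within a line are dropped (keeping first occurrence)
    with a warning; a line with fewer than three fields is a parse error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no members")
            seen: dict[str, None] = {}
            for m in members:
                if m in seen:
                    warnings.warn(f"{path}: line {lineno}: duplicate member {m!r} in {name!r}")
                else:
                    seen[m] = None
            sets.append(GeneSet(name=name, description=description, members=tuple(seen)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column TSV (probe_id, gene_id)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns probe_id and gene_id")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{path}: probe {dup!r} maps to more than one gene")
    return ProbeAnnotation(mapping=dict(zip(df["probe_id"], df["gene_id"])))


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def collapse_probes(matrix: ExpressionMatrix, annotation: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by largest across-sample IQR.

    For each gene with several probes, exactly the probe whose interquartile
    range (Q3 - Q1, linear-interpolation quantiles) across samples is largest
    is kept; IQR ties break to the lexicographically smallest probe id.
    Probes absent from the annotation are dropped (count logged).
    """
    probes = matrix.data.index
    annotated = [p for p in probes if p in annotation.mapping]
    n_dropped = len(probes) - len(annotated)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unannotated probes", n_dropped)
    if not annotated:
        raise DegenerateDataError("no probe in the matrix is present in the annotation")

    sub = matrix.data.loc[annotated]
    values = sub.to_numpy(dtype=float)
    q1, q3 = np.percentile(values, [25, 75], axis=1)
    iqr = pd.Series(q3 - q1, index=sub.index)
    genes = pd.Series([annotation.mapping[p] for p in annotated], index=sub.index)

    keep: list[str] = []
    for _, probe_group in sorted(genes.groupby(genes).groups.items()):
        # argmax IQR; ties -> lexicographically smallest probe id
        candidates = sorted(probe_group)
        best_iqr = max(iqr[p] for p in candidates)
        keep.append(min(p for p in candidates if iqr[p] == best_iqr))

    collapsed = sub.loc[keep]
    collapsed.index = [genes[p] for p in keep]
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(data=collapsed, scale=matrix.scale)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share one empirical distribution (sorted-row means).

    Each column's sorted values are replaced by the across-column means of the
    column-sorted matrix; tied values within a column receive the mean of the
    sorted-row means at the tied positions, so the operation is deterministic
    and idempotent. Requires at least two samples.
    """
    if matrix.data.shape[1] < 2:
        raise DegenerateDataError("quantile normalization requires at least 2 samples")
    values = matrix.data.to_numpy(dtype=float)
    sorted_means = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(sorted_means)
        ranked[order] = sorted_means
        # average sorted-row means over ties
        uniq, inverse = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inverse, weights=ranked)
            counts = np.bincount(inverse)
            ranked = (sums / counts)[inverse]
        out[:, j] = ranked

    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    scale = matrix.scale if matrix.scale != "counts" else "intensity"
    return ExpressionMatrix(data=df, scale=scale)


def log_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) transform of a counts matrix.

    value = log2(1e6 * x_gs / L_s + 1) with L_s the library size (column sum).
    """
    if matrix.scale != "counts":
        raise ValueError(f"log_cpm requires a counts-scale matrix, got scale={matrix.scale!r}")
    lib = matrix.data.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise DegenerateDataError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = matrix.data.div(lib, axis=1) * 1e6
    return ExpressionMatrix(data=np.log2(cpm + 1.0), scale="log2")


def as_log_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix on a non-negative log-like scale (log-CPM for counts)."""
    if matrix.scale == "counts":
        return log_cpm(matrix)
    return matrix
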