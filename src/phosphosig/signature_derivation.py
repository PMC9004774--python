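"""Derivation of up/down transcriptional gene sets anchored to a phospho antibody.

The derivation proceeds in four steps: (1) dichotomize samples into high vs
low phosphorylation by a quantile cut on the anchor antibody; (2) test each
gene for differential expression between the two classes (Welch t on log2
values, BH-adjusted); (3) correlate each gene's expression with the anchor
antibody level across samples; (4) keep genes that are both differentially
expressed and significantly correlated with a sign consistent with their
fold-change direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, EmptySignatureError, MissingAntibodyError
from .omics_io import ExpressionMatrix, RPPAMatrix, as_log_scale

logger = logging.getLogger(__name__)


@dataclass
class PhosphoStratification:
    """High/low phosphorylation labels from a quantile cut on one antibody."""

    antibody_id: str
    labels: pd.Series       # index: sample_id; values in {"high", "low"}
    quantile: float
    cut_value: float

    def __post_init__(self) -> None:
        classes = set(self.labels.unique())
        if classes != {"high", "low"}:
            raise ValueError(f"both classes must be non-empty, got labels {sorted(classes)}")

    def samples(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class DEResult:
    """Per-gene Welch differential expression between high and low classes.

    Columns: log2_fc (mean high - mean low), statistic, p, fdr, zero_variance
    (True where both classes were constant so no test was possible).
    """

    table: pd.DataFrame
    n_high: int
    n_low: int


@dataclass
class CorrelationResult:
    """Per-gene correlation of expression with the anchor antibody values.

    Zero-variance genes are excluded from the table and listed separately.
    """

    table: pd.DataFrame  # columns: r, p
    antibody_id: str
    method: str
    excluded_zero_variance: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneSignature:
    """Final up/down gene sets plus derivation provenance."""

    name: str
    up: frozenset[str]
    down: frozenset[str]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")
        if not self.up or not self.down:
            raise ValueError("a scoring signature requires non-empty up and down sets")


def stratify_by_phospho(
    rppa: RPPAMatrix, antibody: str, q: float = 0.5
) -> PhosphoStratification:
    """Label samples high (> q-quantile of the antibody values) or low.

    The default median split stands in for the phosphorylated vs
    non-phosphorylated dichotomy; the cut value is recorded.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if antibody not in rppa.antibody_ids:
        raise MissingAntibodyError([antibody])
    values = rppa.data.loc[antibody]
    if values.nunique() == 1:
        raise DegenerateDataError(
            f"all samples have identical {antibody} values; no stratification possible"
        )
    cut = float(np.quantile(values.to_numpy(dtype=float), q))
    labels = pd.Series(np.where(values > cut, "high", "low"), index=values.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise DegenerateDataError(
            f"quantile cut q={q} leaves an empty class for antibody {antibody}"
        )
    return PhosphoStratification(antibody_id=antibody, labels=labels, quantile=q, cut_value=cut)


def differential_expression(
    expr: ExpressionMatrix, strat: PhosphoStratification
) -> DEResult:
    """Welch two-sample t per gene (high vs low) on log2 values, BH-adjusted.

    Counts matrices are log-CPM transformed first. Genes constant within both
    classes are untestable: they get p = 1 and a zero_variance flag.
    """
    expr = as_log_scale(expr)
    high = strat.samples("high")
    low = strat.samples("low")
    high = [s for s in high if s in expr.sample_ids]
    low = [s for s in low if s in expr.sample_ids]
    if len(high) < 2 or len(low) < 2:
        raise DegenerateDataError(
            f"need >=2 samples per class, got high={len(high)}, low={len(low)}"
        )
    xh = expr.data[high].to_numpy(dtype=float)
    xl = expr.data[low].to_numpy(dtype=float)

    log2_fc = xh.mean(axis=1) - xl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(xh, xl, axis=1, equal_var=False)
    statistic = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    zero_var = (xh.var(axis=1) == 0) & (xl.var(axis=1) == 0)
    statistic[zero_var] = np.nan
    p[zero_var] = 1.0
    p = np.nan_to_num(p, nan=1.0)

    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "statistic": statistic,
            "p": p,
            "fdr": fdr,
            "zero_variance": zero_var,
        },
        index=expr.data.index,
    )
    return DEResult(table=table, n_high=len(high), n_low=len(low))


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, axis, a)


def mrna_phospho_correlation(
    expr: ExpressionMatrix,
    rppa: RPPAMatrix,
    antibody: str,
    method: str = "spearman",
) -> CorrelationResult:
    """Per-gene correlation between expression and the anchor antibody values.

    Spearman (default) or Pearson over the shared samples; the p-value uses
    the t-transform with n-2 degrees of freedom. Zero-variance genes are
    flagged and excluded from the result table.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson|spearman, got {method!r}")
    if antibody not in rppa.antibody_ids:
        raise MissingAntibodyError([antibody])
    expr = as_log_scale(expr)
    shared = [s for s in expr.sample_ids if s in set(rppa.sample_ids)]
    if len(shared) < 3:
        raise DegenerateDataError(f"only {len(shared)} shared samples; need at least 3")

    x = expr.data[shared].to_numpy(dtype=float)       # genes x n
    y = rppa.data.loc[antibody, shared].to_numpy(dtype=float)
    n = len(shared)
    if np.std(y) == 0:
        raise DegenerateDataError(f"anchor antibody {antibody} has zero variance")

    zero_var = x.std(axis=1) == 0
    if method == "spearman":
        x = _rank(x, axis=1)
        y = stats.rankdata(y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    table = pd.DataFrame({"r": r, "p": p}, index=expr.data.index)
    excluded = tuple(table.index[zero_var])
    if len(excluded):
        logger.info("mrna_phospho_correlation: excluding %d zero-variance genes", len(excluded))
    table = table.loc[~zero_var]
    return CorrelationResult(
        table=table, antibody_id=antibody, method=method, excluded_zero_variance=excluded
    )


def assemble_signature(
    de: DEResult,
    corr: CorrelationResult,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    p_max: float = 0.05,
    name: str = "signature",
) -> GeneSignature:
    """Intersect the DE and correlation filters into up/down gene sets.

    up:   log2FC >= lfc_min, FDR <= fdr_max, r > 0, correlation p <= p_max
    down: log2FC <= -lfc_min, FDR <= fdr_max, r < 0, correlation p <= p_max

    Genes whose correlation sign contradicts their fold-change direction are
    excluded and counted in the provenance. Raises
    :class:`~phosphosig.errors.EmptySignatureError` (carrying the selected
    sizes and nearest-miss values) if either set comes out empty.
    """
    merged = de.table.join(corr.table, how="inner", lsuffix="_de")
    de_up = (merged.log2_fc >= lfc_min) & (merged.fdr <= fdr_max)
    de_down = (merged.log2_fc <= -lfc_min) & (merged.fdr <= fdr_max)
    corr_ok = merged.p <= p_max

    up = merged.index[de_up & corr_ok & (merged.r > 0)]
    down = merged.index[de_down & corr_ok & (merged.r < 0)]
    discordant = int((de_up & corr_ok & (merged.r < 0)).sum()) + int(
        (de_down & corr_ok & (merged.r > 0)).sum()
    )

    provenance = {
        "anchor_antibody": corr.antibody_id,
        "correlation_method": corr.method,
        "lfc_min": lfc_min,
        "fdr_max": fdr_max,
        "p_max": p_max,
        "n_discordant_excluded": discordant,
        "n_genes_tested": int(len(merged)),
        "n_high": de.n_high,
        "n_low": de.n_low,
    }
    if len(up) == 0 or len(down) == 0:
        best_up = merged.log2_fc.max() if len(merged) else float("nan")
        best_down = merged.log2_fc.min() if len(merged) else float("nan")
        best_fdr = merged.fdr.min() if len(merged) else float("nan")
        raise EmptySignatureError(
            up_size=len(up),
            down_size=len(down),
            detail=(
                f"nearest miss: max log2FC={best_up:.3g}, min log2FC={best_down:.3g}, "
                f"min FDR={best_fdr:.3g} at lfc_min={lfc_min}, fdr_max={fdr_max}, p_max={p_max}"
            ),
        )
    return GeneSignature(
        name=name, up=frozenset(up), down=frozenset(down), provenance=provenance
    )
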