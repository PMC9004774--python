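"""Clinical stratification and nonparametric comparison of signature scores.

Samples are binned into BMI classes (normal-weight < 25, overweight [25, 30),
obese >= 30 kg/m2) and a menopause status inferred from age (premenopausal
below 49 years), the proxy rule used for public cohorts without hormonal
records. Final scores are compared between every unordered pair of BMI
classes with a two-sided Wilcoxon rank-sum test — exact when the combined
sample size is at most 20 and there are no ties, otherwise a normal
approximation with continuity and tie correction — optionally within each
menopause stratum, with BH adjustment across the reported family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PhosphosigError
from .omics_io import ClinicalTable
from .signature_scoring import ScoreVector

logger = logging.getLogger(__name__)

BMI_CLASSES = ("normal-weight", "overweight", "obese")
EXACT_CUTOFF = 20  # combined n at or below which the exact null is enumerated


def classify_bmi(bmi: float) -> str:
    """BMI class: <25 normal-weight, [25, 30) overweight, >=30 obese."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 25:
        return "normal-weight"
    if bmi < 30:
        return "overweight"
    return "obese"


def classify_menopause(age: float) -> str:
    """Inferred menopause status: premenopausal below 49 years, else post."""
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    return "pre" if age < 49 else "post"


@dataclass
class GroupAssignment:
    """Per-sample BMI class and inferred menopause status."""

    table: pd.DataFrame  # index sample_id; columns bmi_class, menopause
    n_excluded_missing_bmi: int = 0


def assign_groups(clinical: ClinicalTable) -> GroupAssignment:
    """Classify every sample with clinical data; samples lacking BMI are
    excluded and counted."""
    df = clinical.data
    has_bmi = df["bmi"].notna()
    excluded = int((~has_bmi).sum())
    if excluded:
        logger.info("assign_groups: excluding %d samples without BMI", excluded)
    sub = df.loc[has_bmi]
    out = pd.DataFrame(
        {
            "bmi_class": [classify_bmi(b) for b in sub["bmi"]],
            "menopause": [classify_menopause(a) for a in sub["age"]],
        },
        index=sub.index,
    )
    return GroupAssignment(table=out, n_excluded_missing_bmi=excluded)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float       # Mann-Whitney U of group_a
    p: float               # two-sided
    p_adjusted: float | None
    median_a: float
    median_b: float
    method: str            # "exact" or "asymptotic"
    stratum: str = "all"

    @property
    def direction(self) -> str:
        if self.median_a == self.median_b:
            return "none"
        return f"{self.group_a} > {self.group_b}" if self.median_a > self.median_b else (
            f"{self.group_b} > {self.group_a}"
        )


def wilcoxon_rank_sum(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with the exact/asymptotic
    rule: exact for combined n <= EXACT_CUTOFF without ties, else a normal
    approximation with continuity and tie correction.

    Returns (U statistic of x, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_CUTOFF and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), method


def compare_groups(
    scores: ScoreVector | pd.Series,
    assignment: GroupAssignment,
    stratify_by_menopause: bool = False,
    adjust: str = "BH",
) -> list[GroupComparison]:
    """Wilcoxon comparison of final scores for every unordered BMI-class pair.

    With ``stratify_by_menopause`` the pairs are tested inside each menopause
    stratum. Pairs where either group has fewer than 2 scored samples are
    skipped with a log message. ``adjust`` is "BH" (default) or "none";
    adjustment spans the whole reported family.
    """
    if adjust not in ("BH", "none"):
        raise ValueError(f"adjust must be BH|none, got {adjust!r}")
    values = scores.final_score if isinstance(scores, ScoreVector) else scores
    shared = values.index.intersection(assignment.table.index)
    values = values.loc[shared]
    groups = assignment.table.loc[shared]

    strata = ["pre", "post"] if stratify_by_menopause else ["all"]
    comparisons: list[GroupComparison] = []
    for stratum in strata:
        mask = (groups["menopause"] == stratum) if stratum != "all" else pd.Series(
            True, index=groups.index
        )
        for ga, gb in itertools.combinations(BMI_CLASSES, 2):
            xa = values[mask & (groups["bmi_class"] == ga)]
            xb = values[mask & (groups["bmi_class"] == gb)]
            if len(xa) < 2 or len(xb) < 2:
                logger.info(
                    "compare_groups: skipping %s vs %s (stratum %s): n=%d vs %d",
                    ga, gb, stratum, len(xa), len(xb),
                )
                continue
            u, p, method = wilcoxon_rank_sum(xa, xb)
            comparisons.append(
                GroupComparison(
                    group_a=ga,
                    group_b=gb,
                    n_a=len(xa),
                    n_b=len(xb),
                    statistic=u,
                    p=p,
                    p_adjusted=None,
                    median_a=float(xa.median()),
                    median_b=float(xb.median()),
                    method=method,
                    stratum=stratum,
                )
            )
    if comparisons:
        if adjust == "BH":
            adj = multipletests([c.p for c in comparisons], method="fdr_bh")[1]
        else:
            adj = [c.p for c in comparisons]
        for c, pa in zip(comparisons, adj):
            c.p_adjusted = float(pa)
    return comparisons


def build_report(
    scores: ScoreVector | pd.Series,
    assignment: GroupAssignment,
    comparisons: list[GroupComparison],
) -> pd.DataFrame:
    """Tabular report: per-group summaries then pairwise comparison rows.

    Summary rows carry n, median and IQR of the final score per BMI class;
    comparison rows carry group sizes, the U statistic, raw and adjusted p.
    The table round-trips through TSV.
    """
    values = scores.final_score if isinstance(scores, ScoreVector) else scores
    shared = values.index.intersection(assignment.table.index)
    values = values.loc[shared]
    groups = assignment.table.loc[shared]

    rows: list[dict] = []
    for cls in BMI_CLASSES:
        x = values[groups["bmi_class"] == cls]
        if len(x) == 0:
            continue
        q1, med, q3 = np.percentile(x.to_numpy(), [25, 50, 75])
        rows.append(
            {
                "row_type": "summary",
                "group_a": cls,
                "group_b": "",
                "stratum": "all",
                "n_a": len(x),
                "n_b": "",
                "median_a": med,
                "median_b": "",
                "iqr": q3 - q1,
                "statistic": "",
                "p": "",
                "p_adjusted": "",
                "method": "",
            }
        )
    for c in comparisons:
        rows.append(
            {
                "row_type": "comparison",
                "group_a": c.group_a,
                "group_b": c.group_b,
                "stratum": c.stratum,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "median_a": c.median_a,
                "median_b": c.median_b,
                "iqr": "",
                "statistic": c.statistic,
                "p": c.p,
                "p_adjusted": c.p_adjusted,
                "method": c.method,
            }
        )
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.17g")
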