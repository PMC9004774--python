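"""Sum-based phospho-protein pathway activity scores from RPPA data.

A pathway activity score for a sample is the plain sum of its normalized
phospho-antibody values over a defined antibody set; the input is assumed to be
level-3-like (already normalized), so no re-normalization happens before the
sum. Built-in definitions cover the AKT axis (Akt pS473/pT308, GSK3 pS9 and
pS21/S9, PRAS40 pT246) and the mTOR axis (AKT plus mTOR, 4EBP1 pS65/pT37-T46/
pT70, RICTOR pT3135, S6 pS235/S236 and pS240/S244).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, MissingAntibodyError
from .omics_io import RPPAMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhosphoTarget:
    """One phospho (or total) antibody: canonical id, protein, residue string."""

    antibody_id: str
    protein: str
    residue: str = ""  # empty for total-protein antibodies


def _t(antibody_id: str, protein: str, residue: str = "") -> PhosphoTarget:
    return PhosphoTarget(antibody_id=antibody_id, protein=protein, residue=residue)


AKT_TARGETS: tuple[PhosphoTarget, ...] = (
    _t("AKT_pS473", "Akt", "S473"),
    _t("AKT_pT308", "Akt", "T308"),
    _t("GSK3_pS9", "GSK3", "S9"),
    _t("GSK3_pS21S9", "GSK3", "S21/S9"),
    _t("PRAS40_pT246", "PRAS40", "T246"),
)

MTOR_EXTRA_TARGETS: tuple[PhosphoTarget, ...] = (
    _t("MTOR", "mTOR"),
    _t("4EBP1_pS65", "4EBP1", "S65"),
    _t("4EBP1_pT37T46", "4EBP1", "T37/T46"),
    _t("4EBP1_pT70", "4EBP1", "T70"),
    _t("RICTOR_pT3135", "RICTOR", "T3135"),
    _t("S6_pS235S236", "S6", "S235/S236"),
    _t("S6_pS240S244", "S6", "S240/S244"),
)


@dataclass(frozen=True)
class PathwayDefinition:
    """A named set of phospho targets whose levels are summed per sample."""

    name: str
    targets: tuple[PhosphoTarget, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"pathway {self.name!r} has no targets")
        ids = [t.antibody_id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pathway {self.name!r} has duplicate antibody ids")

    @property
    def antibody_ids(self) -> list[str]:
        return [t.antibody_id for t in self.targets]


AKT_PATHWAY = PathwayDefinition(name="AKT", targets=AKT_TARGETS)
MTOR_PATHWAY = PathwayDefinition(name="MTOR", targets=AKT_TARGETS + MTOR_EXTRA_TARGETS)

BUILTIN_PATHWAYS: dict[str, PathwayDefinition] = {
    "AKT": AKT_PATHWAY,
    "MTOR": MTOR_PATHWAY,
}


@dataclass
class ActivityScoreVector:
    """Per-sample pathway activity (sum of antibody values) and coverage."""

    pathway: str
    scores: pd.Series  # index: sample_id
    coverage: float  # fraction of pathway antibodies found in the matrix
    antibodies_used: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")


def canonical_antibody_id(raw: str, aliases: dict[str, str] | None = None) -> str:
    """Map a platform antibody label onto the canonical PROTEIN_pRESIDUE form.

    Matching is exact after upper-casing and stripping separator characters;
    a user-supplied alias table (raw label -> canonical id) takes precedence.
    """
    if aliases and raw in aliases:
        return aliases[raw]
    key = raw.strip().upper().replace("-", "").replace(" ", "")
    if aliases:
        normalized_aliases = {
            k.strip().upper().replace("-", "").replace(" ", ""): v for k, v in aliases.items()
        }
        if key in normalized_aliases:
            return normalized_aliases[key]
    return key


def pathway_activity(
    rppa: RPPAMatrix,
    pathway: PathwayDefinition,
    missing_policy: str = "strict",
    aliases: dict[str, str] | None = None,
) -> ActivityScoreVector:
    """Score each sample as the sum of its pathway antibody values.

    ``missing_policy='strict'`` raises if any pathway antibody is absent from
    the matrix; ``'lenient'`` skips absent antibodies with a logged warning
    and records the resulting coverage.
    """
    if missing_policy not in ("strict", "lenient"):
        raise ValueError(f"missing_policy must be strict|lenient, got {missing_policy!r}")
    row_index = {canonical_antibody_id(a, aliases): a for a in rppa.antibody_ids}
    present, missing = [], []
    for wanted in pathway.antibody_ids:
        key = canonical_antibody_id(wanted, aliases)
        (present if key in row_index else missing).append(wanted)
    if not present:
        raise MissingAntibodyError(missing)
    if missing:
        if missing_policy == "strict":
            raise MissingAntibodyError(
                missing,
                f"pathway {pathway.name!r}: antibodies missing under strict policy: "
                f"{', '.join(missing)}",
            )
        logger.warning(
            "pathway %s: skipping %d absent antibodies: %s",
            pathway.name, len(missing), ", ".join(missing),
        )
    rows = [row_index[canonical_antibody_id(a, aliases)] for a in present]
    scores = rppa.data.loc[rows].sum(axis=0)
    return ActivityScoreVector(
        pathway=pathway.name,
        scores=scores,
        coverage=len(present) / len(pathway.antibody_ids),
        antibodies_used=tuple(rows),
    )


def score_correlation(
    a: ActivityScoreVector | pd.Series,
    b: pd.Series,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlate an activity score with any per-sample quantity.

    Computed over the intersection of sample ids; returns (r, p) with p from
    the t-transform (Pearson) or scipy's Spearman approximation.
    """
    sa = a.scores if isinstance(a, ActivityScoreVector) else a
    shared = sa.index.intersection(b.index)
    if len(shared) < 3:
        raise DegenerateDataError(f"only {len(shared)} shared samples; need at least 3")
    x = sa.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in one of the correlated vectors")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be pearson|spearman, got {method!r}")
    return float(res.statistic), float(res.pvalue)
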