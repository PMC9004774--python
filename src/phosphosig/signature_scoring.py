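"""Ratio-of-means signature scoring with cohort-level z-scaling.

For each sample the mean expression of the signature's up genes (muUP) and of
its down genes (muDW) are computed independently; score1 = muUP / muDW, and
the final score is the z-scaling of score1 across all samples of the cohort
being scored (population SD). Counts matrices are log-CPM(+1) transformed
first so every value is non-negative and the ratio is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateDataError
from .omics_io import ExpressionMatrix, as_log_scale
from .signature_derivation import GeneSignature

logger = logging.getLogger(__name__)

_DENOM_EPS = 1e-8


@dataclass
class ScoreVector:
    """Per-sample signature scores and the coverage achieved.

    ``table`` columns: mu_up, mu_down, score1 and (after z-scaling)
    final_score, indexed by sample id.
    """

    table: pd.DataFrame
    coverage_up: float
    coverage_down: float
    provenance: dict = field(default_factory=dict)

    @property
    def score1(self) -> pd.Series:
        return self.table["score1"]

    @property
    def final_score(self) -> pd.Series:
        return self.table["final_score"]


def score_samples(
    expr: ExpressionMatrix, signature: GeneSignature, min_coverage: float = 0.5
) -> ScoreVector:
    """Compute muUP, muDW and score1 = muUP/muDW for every sample.

    Signature genes absent from the matrix are logged; each set's coverage
    must reach ``min_coverage``. A sample whose muDW is ~0 (<= 1e-8) has no
    defined ratio and raises.
    """
    expr = as_log_scale(expr)
    found_up = sorted(signature.up & set(expr.gene_ids))
    found_down = sorted(signature.down & set(expr.gene_ids))
    cov_up = len(found_up) / len(signature.up)
    cov_down = len(found_down) / len(signature.down)
    for set_name, found, total, cov in (
        ("up", found_up, signature.up, cov_up),
        ("down", found_down, signature.down, cov_down),
    ):
        missing = len(total) - len(found)
        if missing:
            logger.info("score_samples: %d of %d %s genes missing", missing, len(total), set_name)
        if not found:
            raise CoverageError(f"no {set_name}-set gene of {signature.name!r} found in matrix")
        if cov < min_coverage:
            raise CoverageError(
                f"{set_name}-set coverage {cov:.2f} below min_coverage={min_coverage} "
                f"for signature {signature.name!r}"
            )

    mu_up = expr.data.loc[found_up].mean(axis=0)
    mu_down = expr.data.loc[found_down].mean(axis=0)
    bad = mu_down[mu_down <= _DENOM_EPS]
    if len(bad):
        raise DegenerateDataError(
            f"non-positive down-set mean for sample(s) {list(bad.index)[:5]}; "
            "score1 is undefined"
        )
    table = pd.DataFrame({"mu_up": mu_up, "mu_down": mu_down, "score1": mu_up / mu_down})
    return ScoreVector(
        table=table,
        coverage_up=cov_up,
        coverage_down=cov_down,
        provenance={"signature": signature.name, "min_coverage": min_coverage},
    )


def zscale(score1: pd.Series) -> pd.Series:
    """z-scale score1 across the cohort: (x - mean) / population SD."""
    if len(score1) < 2:
        raise DegenerateDataError("z-scaling requires at least 2 samples")
    x = score1.to_numpy(dtype=float)
    sd = x.std()  # population (ddof=0)
    if sd == 0:
        raise DegenerateDataError("zero variance in score1; degenerate cohort")
    return pd.Series((x - x.mean()) / sd, index=score1.index, name="final_score")


def score_cohort(
    expr: ExpressionMatrix, signature: GeneSignature, min_coverage: float = 0.5
) -> ScoreVector:
    """score_samples followed by cohort-level z-scaling (the final score)."""
    sv = score_samples(expr, signature, min_coverage=min_coverage)
    sv.table["final_score"] = zscale(sv.table["score1"])
    return sv


def write_scores(sv: ScoreVector, path) -> None:
    """Write a scores TSV: sample_id, mu_up, mu_down, score1, final_score, coverage."""
    out = sv.table.copy()
    out["coverage_up"] = sv.coverage_up
    out["coverage_down"] = sv.coverage_down
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
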