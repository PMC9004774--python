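import numpy as np
import pandas as pd
import pytest

from phosphosig import (
    ANCHOR_ANTIBODY,
    ExpressionMatrix,
    RPPAMatrix,
    SimulationConfig,
    differential_expression,
    generate_cohort,
    mrna_phospho_correlation,
    stratify_by_phospho,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One standard-conditions cohort (200 samples, 2000 genes, 50+50 planted)."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def derived(default_cohort):
    """Stratification, DE and correlation results on the standard cohort."""
    c = default_cohort
    strat = stratify_by_phospho(c.rppa, ANCHOR_ANTIBODY, q=0.5)
    de = differential_expression(c.expression, strat)
    corr = mrna_phospho_correlation(c.expression, c.rppa, ANCHOR_ANTIBODY)
    return strat, de, corr


@pytest.fixture
def small_expr():
    """3 genes x 4 samples log2-scale matrix with easy numbers."""
    data = pd.DataFrame(
        [[6.0, 5.0, 4.0, 3.0], [4.0, 5.0, 2.0, 1.0], [2.0, 2.5, 1.0, 0.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data=data, scale="log2")


@pytest.fixture
def small_rppa():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.5, -0.5, 0.1, -0.1]],
        index=[ANCHOR_ANTIBODY, "DECOY1_pX1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return RPPAMatrix(data=data)


def make_expression(values, scale="log2", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples), scale=scale
    )
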