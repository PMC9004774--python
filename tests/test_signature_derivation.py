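import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphosig import (
    ANCHOR_ANTIBODY,
    DegenerateDataError,
    EmptySignatureError,
    MissingAntibodyError,
    RPPAMatrix,
    SimulationConfig,
    assemble_signature,
    differential_expression,
    generate_cohort,
    mrna_phospho_correlation,
    stratify_by_phospho,
)
from phosphosig.signature_derivation import (
    CorrelationResult,
    DEResult,
    PhosphoStratification,
)

from .conftest import make_expression
from .oracles import spearman_r, welch_t


def rppa_single(values, samples, antibody=ANCHOR_ANTIBODY):
    return RPPAMatrix(
        data=pd.DataFrame([values], index=[antibody], columns=samples).astype(float)
    )


class TestStratify:
    def test_median_split(self):
        rppa = rppa_single([1, 2, 3, 4], list("abcd"))
        strat = stratify_by_phospho(rppa, ANCHOR_ANTIBODY, q=0.5)
        assert set(strat.samples("low")) == {"a", "b"}
        assert set(strat.samples("high")) == {"c", "d"}
        assert strat.cut_value == pytest.approx(2.5)

    def test_upper_quartile_split(self):
        rppa = rppa_single([1, 2, 3, 4], list("abcd"))
        strat = stratify_by_phospho(rppa, ANCHOR_ANTIBODY, q=0.75)
        assert set(strat.samples("high")) == {"d"}

    def test_constant_values_error(self):
        rppa = rppa_single([2, 2, 2, 2], list("abcd"))
        with pytest.raises(DegenerateDataError):
            stratify_by_phospho(rppa, ANCHOR_ANTIBODY)

    def test_missing_antibody(self):
        rppa = rppa_single([1, 2, 3], list("abc"))
        with pytest.raises(MissingAntibodyError):
            stratify_by_phospho(rppa, "NOPE_pS1")

    def test_high_group_has_higher_latent_activity(self):
        hits = 0
        for seed in range(20):
            c = generate_cohort(SimulationConfig(n_samples=200, n_genes=50, n_up=5,
                                                 n_down=5, seed=seed))
            strat = stratify_by_phospho(c.rppa, ANCHOR_ANTIBODY)
            lat = c.truth.latent_activity
            hits += lat[strat.samples("high")].mean() > lat[strat.samples("low")].mean()
        assert hits == 20


class TestDifferentialExpression:
    def strat_for(self, samples, n_high):
        labels = pd.Series(
            ["high"] * n_high + ["low"] * (len(samples) - n_high), index=samples
        )
        return PhosphoStratification(
            antibody_id=ANCHOR_ANTIBODY, labels=labels, quantile=0.5, cut_value=0.0
        )

    def test_log2fc_and_statistic_match_welch_formula(self):
        high, low = [10.0, 10.1, 9.9], [6.0, 6.1, 5.9]
        m = make_expression([high + low], samples=[f"s{i}" for i in range(6)])
        de = differential_expression(m, self.strat_for(m.sample_ids, 3))
        row = de.table.iloc[0]
        assert row.log2_fc == pytest.approx(4.0, abs=1e-10)
        t_expected, df_expected = welch_t(high, low)
        assert row.statistic == pytest.approx(t_expected, abs=1e-10)
        assert row.p == pytest.approx(2 * stats.t.sf(abs(t_expected), df_expected), abs=1e-10)

    def test_zero_variance_gene_flagged_p_one(self):
        m = make_expression(
            [[5, 5, 5, 5, 5, 5], [1, 2, 3, 1, 2, 3]], samples=[f"s{i}" for i in range(6)]
        )
        de = differential_expression(m, self.strat_for(m.sample_ids, 3))
        assert de.table.iloc[0].zero_variance
        assert de.table.iloc[0].p == 1.0
        assert de.table.iloc[0].log2_fc == 0.0
        assert not de.table.iloc[1].zero_variance

    def test_bh_adjustment_is_monotone_and_bounded(self, derived):
        _, de, _ = derived
        t = de.table
        assert ((t.fdr >= t.p - 1e-15) & (t.fdr <= 1.0)).all()

    def test_small_class_errors(self):
        m = make_expression([[1, 2, 3]], samples=list("abc"))
        with pytest.raises(DegenerateDataError, match="high=1"):
            differential_expression(m, self.strat_for(list("abc"), 1))

    def test_null_type_one_error_rate(self):
        c = generate_cohort(SimulationConfig(beta=0.0, seed=123))
        strat = stratify_by_phospho(c.rppa, ANCHOR_ANTIBODY)
        de = differential_expression(c.expression, strat)
        frac = (de.table.p < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)


class TestCorrelation:
    def test_exact_copy_and_negation(self):
        samples = [f"s{i}" for i in range(6)]
        anchor = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        m = make_expression([anchor, [-v for v in anchor]], samples=samples)
        rppa = rppa_single(anchor, samples)
        res = mrna_phospho_correlation(m, rppa, ANCHOR_ANTIBODY, method="spearman")
        assert res.table.loc["g1", "r"] == pytest.approx(1.0, abs=1e-12)
        assert res.table.loc["g2", "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_rank_correlation(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(6)]
        values = rng.normal(size=(4, 6))
        anchor = rng.normal(size=6)
        m = make_expression(values, samples=samples)
        rppa = rppa_single(anchor, samples)
        res = mrna_phospho_correlation(m, rppa, ANCHOR_ANTIBODY, method="spearman")
        for i, gene in enumerate(m.gene_ids):
            assert res.table.loc[gene, "r"] == pytest.approx(
                spearman_r(values[i], anchor), abs=1e-12
            )
            scipy_res = stats.spearmanr(values[i], anchor)
            assert res.table.loc[gene, "p"] == pytest.approx(scipy_res.pvalue, abs=1e-9)

    def test_zero_variance_gene_excluded(self):
        samples = [f"s{i}" for i in range(5)]
        m = make_expression([[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]], samples=samples)
        rppa = rppa_single([2.0, 1.0, 4.0, 3.0, 5.0], samples)
        res = mrna_phospho_correlation(m, rppa, ANCHOR_ANTIBODY)
        assert res.excluded_zero_variance == ("g1",)
        assert list(res.table.index) == ["g2"]

    def test_too_few_shared_samples(self):
        m = make_expression([[1, 2]], samples=["a", "b"])
        rppa = rppa_single([1.0, 2.0], ["a", "b"])
        with pytest.raises(DegenerateDataError, match="shared"):
            mrna_phospho_correlation(m, rppa, ANCHOR_ANTIBODY)


def _mini_results(rows):
    """rows: dict gene -> (log2_fc, fdr, r, p_corr)."""
    genes = list(rows)
    de = DEResult(
        table=pd.DataFrame(
            {
                "log2_fc": [rows[g][0] for g in genes],
                "statistic": 1.0,
                "p": [rows[g][1] for g in genes],
                "fdr": [rows[g][1] for g in genes],
                "zero_variance": False,
            },
            index=genes,
        ),
        n_high=10,
        n_low=10,
    )
    corr = CorrelationResult(
        table=pd.DataFrame(
            {"r": [rows[g][2] for g in genes], "p": [rows[g][3] for g in genes]},
            index=genes,
        ),
        antibody_id=ANCHOR_ANTIBODY,
        method="spearman",
    )
    return de, corr


class TestAssembleSignature:
    def test_rule_application_up_down_discordant(self):
        de, corr = _mini_results(
            {
                "up_ok": (2.0, 0.01, 0.6, 0.001),
                "down_ok": (-2.0, 0.01, -0.6, 0.001),
                "discordant": (2.0, 0.01, -0.6, 0.001),
                "weak_fc": (0.5, 0.01, 0.6, 0.001),
                "bad_fdr": (2.0, 0.5, 0.6, 0.001),
                "bad_corr_p": (2.0, 0.01, 0.6, 0.5),
            }
        )
        sig = assemble_signature(de, corr, lfc_min=1.0, fdr_max=0.05, p_max=0.05)
        assert sig.up == {"up_ok"}
        assert sig.down == {"down_ok"}
        assert sig.provenance["n_discordant_excluded"] == 1

    def test_empty_set_error_reports_sizes_and_nearest_miss(self):
        de, corr = _mini_results({"up_ok": (2.0, 0.01, 0.6, 0.001)})
        with pytest.raises(EmptySignatureError, match="down") as err:
            assemble_signature(de, corr)
        assert err.value.up_size == 1 and err.value.down_size == 0

    def test_threshold_monotonicity(self, derived):
        _, de, corr = derived
        loose = assemble_signature(de, corr, lfc_min=0.5, fdr_max=0.1, p_max=0.1)
        tight = assemble_signature(de, corr, lfc_min=1.0, fdr_max=0.05, p_max=0.05)
        assert tight.up <= loose.up
        assert tight.down <= loose.down
        assert not tight.up & tight.down

    def test_planted_recovery(self, default_cohort, derived):
        _, de, corr = derived
        sig = assemble_signature(de, corr)
        truth = default_cohort.truth
        up_t, down_t = truth.planted("up"), truth.planted("down")
        assert len(sig.up & up_t) / len(up_t) >= 0.9
        assert len(sig.down & down_t) / len(down_t) >= 0.9
        assert len(sig.up - up_t) / len(sig.up) <= 0.05
        assert len(sig.down - down_t) / len(sig.down) <= 0.05

    def test_recovery_improves_with_beta(self):
        recovered = []
        for beta in (0.25, 0.5, 1.0):
            c = generate_cohort(SimulationConfig(beta=beta, seed=21))
            strat = stratify_by_phospho(c.rppa, ANCHOR_ANTIBODY)
            de = differential_expression(c.expression, strat)
            corr = mrna_phospho_correlation(c.expression, c.rppa, ANCHOR_ANTIBODY)
            try:
                sig = assemble_signature(de, corr)
                n = len(sig.up & c.truth.planted("up")) + len(
                    sig.down & c.truth.planted("down")
                )
            except EmptySignatureError:
                n = 0
            recovered.append(n)
        assert recovered[0] <= recovered[1] <= recovered[2]
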