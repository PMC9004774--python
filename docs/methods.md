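# Methods

## Generative model of the synthetic cohort

Each simulated sample *i* carries a latent phospho-pathway activity

  a_i ~ Normal(μ_g(i), σ_a²)

where μ_g(i) is a group shift: 0 for normal-weight, ½·δ·σ_a for overweight
and δ·σ_a for obese (`delta_group` = δ, default 1). The intermediate
overweight shift is a package choice — the simulation only pins the obese
shift — and makes the three BMI classes ordered in activity, which is what a
monotone biological dose–response would produce.

The RPPA matrix carries one **anchor antibody** (`AKT_pS473`) measuring
a_i + Normal(0, `rppa_noise_sd`²) plus `n_decoy_antibodies` rows of pure
standard-normal noise, so downstream code is exercised against irrelevant
antibodies.

Gene *g* has a baseline log₂ mean drawn Normal(3, 2²) (i.e. a log-normal
baseline, giving a realistic dynamic range without extra configuration), and
per-sample log₂ mean

  m_gi = baseline_g + s_g · β · a_i,  s_g ∈ {+1 (up), −1 (down), 0 (null)}

with `n_up` and `n_down` planted genes chosen uniformly at random. Per-sample
means are rescaled so each column's expectation equals `mean_library_size`
(default 10⁶), then counts are drawn negative-binomial with variance
m + φ·m² (`dispersion` = φ, default 0.1; Poisson when φ < 10⁻¹²). BMI is
uniform within the class interval ([18.5, 25) / [25, 30) / [30, 45]) and age
is uniform-integer in the pre- (25–48) or post-menopausal (49–75) range,
chosen independently of expression with probability `frac_premenopausal`
(default 0.5) — clinical covariates interact with expression only through
the group label, by design.

Defaults (200 samples, 2000 genes, 50+50 planted, β = 1, σ_a = 1, δ = 1,
noise SD 0.2) are the desk-scale study conditions used by the test suite and
the acceptance script. The same seed reproduces a cohort bit-identically
(single `numpy.random.Generator`, fixed draw order).

What the generator does **not** emulate: batch effects, tumor purity,
probe-level array artifacts, library-size heterogeneity beyond NB noise,
gene–gene correlation beyond the shared latent factor, and survival
outcomes. Passing tests therefore show that the pipeline is correct and
well calibrated under its own model assumptions, not that those assumptions
hold in any particular real cohort.

## Pipeline conventions

**Quantile normalization.** Every column's sorted values are replaced by the
across-column means of the column-sorted matrix. Tied values within a column
receive the mean of the sorted-row means at the tied positions, making the
operation deterministic and idempotent. Requires ≥ 2 samples.

**Probe collapsing.** Among probes mapping to one gene, the probe with the
largest across-sample interquartile range (Q3 − Q1, linear-interpolation
quantiles) is kept; IQR ties break to the lexicographically smallest probe
id. Unannotated probes are dropped with a logged count.

**Counts normalization.** log₂(CPM + 1). This is the internal log scale for
all count matrices (differential expression and scoring); it keeps every
value non-negative so the ratio-of-means statistic is well defined.
Negative-binomial model fits are deliberately not used for differential
expression — the derived gene sets, not the engine, are the object of
interest — and the Welch test below is pluggable if a different engine is
wanted.

**Stratification.** "Phosphorylated vs non-phosphorylated" is a quantile cut
on the anchor antibody; the default q = 0.5 (median split) is configurable.
Samples strictly above the cut are "high".

**Differential expression.** Welch two-sample *t* per gene on the log scale,
log₂FC = mean(high) − mean(low), BH adjustment across all tested genes.
Genes with zero variance in both classes are untestable and are assigned
p = 1 with a `zero_variance` flag (this includes the constant-gene case
where the class means trivially agree).

**mRNA–phospho correlation.** Per-gene Spearman (default; robust to the
mixed scales of counts and RPPA) or Pearson against the anchor antibody over
shared samples; p from the t-transform with n−2 df. Zero-variance genes are
excluded and listed.

**Signature assembly.** up = {log₂FC ≥ lfc_min, FDR ≤ fdr_max, r > 0,
p_corr ≤ p_max}; down is the mirror image. Defaults lfc_min = 1,
fdr_max = 0.05, p_max = 0.05. Genes whose correlation sign contradicts the
fold-change direction are excluded and counted in the provenance rather than
admitted — "correlated" is read as sign-consistent with the expression
change. An empty up or down set raises an error carrying the selected sizes
and nearest-miss threshold values. Signatures anchored to different
antibodies (e.g. Akt pS473 vs pT308) are derived separately; no merge rule
is imposed.

**Scoring.** score1 = μUP/μDW per sample on the non-negative log scale; the
final score is score1 z-scaled across the cohort being scored using the
population (n) SD — the n vs n−1 choice only rescales all cohorts by a
common factor and is fixed for determinism. A down-set mean ≤ 10⁻⁸ makes the
ratio undefined and raises. `min_coverage` (default 0.5 per set) guards
cross-platform application where signature genes are missing from the
matrix.

**Group comparison.** BMI classes partition (0, ∞) as < 25 / [25, 30) / ≥ 30
kg/m²; menopause is inferred from age with "pre" strictly below 49 years
(age exactly 49 is post — the complement of the "< 49" rule taken
literally). Pairwise Wilcoxon rank-sum tests are exact (full enumeration
null) when the combined n ≤ 20 and there are no ties, otherwise a normal
approximation with continuity and tie correction; the exact cutoff of 20
keeps enumeration tractable. BH adjustment spans the whole reported family
(all pairs, both menopause strata when stratified) and can be disabled.
Groups with fewer than two samples are skipped and logged.

## Problem sizes

The test suite and acceptance script run entirely on simulated cohorts of
200 × 2000 (recovery, null calibration, score–latent correlation) and
60 × 600 with 30 obese vs 30 normal-weight samples over 100 replicates
(group-comparison power). These sizes give Monte-Carlo error well inside the
asserted bands while keeping a full run in the tens of seconds.

## Known limitations

* The exact Wilcoxon path enumerates the no-ties null; tied data fall back
  to the asymptotic approximation regardless of n.
* The Spearman p-value uses the t-transform, adequate for n ≳ 10 but
  approximate for very small cohorts.
* Antibody-id matching is exact on a canonicalized `PROTEIN_pRESIDUE` form
  with an optional alias table; no fuzzy matching across RPPA platforms.
* The scoring statistic is the ratio of means only; rank-based single-sample
  enrichment alternatives are out of scope.
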