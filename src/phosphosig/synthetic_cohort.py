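"""Paired expression / RPPA / clinical cohort simulator with ground truth.

The generator emulates the joint structure the analysis assumes: each sample
carries a latent phospho-pathway activity a_i; a designated anchor antibody
measures a_i plus noise (decoy antibodies are pure noise); planted "up" and
"down" gene sets shift their log2 expression mean by +/- beta * a_i; counts are
drawn negative-binomial around those means; BMI-group membership shifts the
latent activity (obese by delta_group standard deviations, overweight by half
that), and BMI / age are drawn within the group's class interval so the
downstream BMI and menopause classifiers see realistic covariates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .omics_io import ClinicalTable, ExpressionMatrix, RPPAMatrix

ANCHOR_ANTIBODY = "AKT_pS473"

_BMI_INTERVALS = {
    "normal-weight": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, 45.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-cohort simulation.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 200 samples, 2000 genes with 50 planted up and 50 planted down,
    unit effect size and latent SD, a one-SD obese shift, and mild RPPA noise.
    """

    n_samples: int = 200
    n_genes: int = 2000
    n_up: int = 50
    n_down: int = 50
    beta: float = 1.0              # log2 expression shift per unit latent activity
    sigma_a: float = 1.0           # latent activity SD
    delta_group: float = 1.0       # obese latent shift, in units of sigma_a
    frac_obese: float = 1 / 3
    frac_overweight: float = 1 / 3
    frac_premenopausal: float = 0.5
    age_range_pre: tuple[int, int] = (25, 48)
    age_range_post: tuple[int, int] = (49, 75)
    mean_library_size: float = 1e6
    dispersion: float = 0.1        # NB overdispersion; Poisson as it -> 0
    rppa_noise_sd: float = 0.2
    n_decoy_antibodies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {getattr(self, name)}")
        for name in ("n_up", "n_down", "n_decoy_antibodies"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n_up + self.n_down > self.n_genes:
            raise ConfigError(
                f"n_up + n_down ({self.n_up + self.n_down}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("sigma_a", "mean_library_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("dispersion", "rppa_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("frac_obese", "frac_overweight", "frac_premenopausal"):
            frac = getattr(self, name)
            if not 0 <= frac <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {frac}")
        if self.frac_obese + self.frac_overweight > 1:
            raise ConfigError(
                "frac_obese + frac_overweight exceeds 1 "
                f"({self.frac_obese} + {self.frac_overweight})"
            )
        for name in ("age_range_pre", "age_range_post"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigError(f"{name} must be a positive (low, high) range, got {(lo, hi)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range_pre"] = list(self.age_range_pre)
        d["age_range_post"] = list(self.age_range_post)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("age_range_pre", "age_range_post"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort: the recovery oracle.

    ``latent_activity`` is the per-sample phospho activity a_i; ``membership``
    labels each gene up / down / null; ``group`` is the per-sample BMI class.
    """

    latent_activity: pd.Series        # index: sample_id
    membership: pd.Series             # index: gene_id; values in {up, down, null}
    group: pd.Series                  # index: sample_id
    config: SimulationConfig

    def __post_init__(self) -> None:
        counts = self.membership.value_counts()
        if counts.get("up", 0) != self.config.n_up or counts.get("down", 0) != self.config.n_down:
            raise ValueError("membership counts do not match the configuration")
        if len(self.latent_activity) != self.config.n_samples:
            raise ValueError("latent_activity length does not match n_samples")

    def planted(self, label: str) -> set[str]:
        return set(self.membership.index[self.membership == label])


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix   # counts
    rppa: RPPAMatrix
    clinical: ClinicalTable
    truth: SyntheticTruth

    def __post_init__(self) -> None:
        ids = set(self.expression.sample_ids)
        for other in (
            set(self.rppa.sample_ids),
            set(self.clinical.sample_ids),
            set(self.truth.latent_activity.index),
        ):
            if other != ids:
                raise ValueError("sample id sets differ across cohort components")


def _group_sizes(config: SimulationConfig) -> dict[str, int]:
    n = config.n_samples
    n_obese = round(config.frac_obese * n)
    n_over = round(config.frac_overweight * n)
    if n_obese + n_over > n:
        n_over = n - n_obese
    return {
        "normal-weight": n - n_obese - n_over,
        "overweight": n_over,
        "obese": n_obese,
    }


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one paired cohort; same seed implies bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{i + 1:04d}" for i in range(g)]

    # group labels (deterministic counts), then latent activity with group shifts
    sizes = _group_sizes(config)
    labels = np.repeat(
        ["normal-weight", "overweight", "obese"],
        [sizes["normal-weight"], sizes["overweight"], sizes["obese"]],
    )
    rng.shuffle(labels)
    group = pd.Series(labels, index=sample_ids, name="group")
    shift = np.select(
        [labels == "obese", labels == "overweight"],
        [config.delta_group * config.sigma_a, 0.5 * config.delta_group * config.sigma_a],
        default=0.0,
    )
    latent = shift + config.sigma_a * rng.standard_normal(n)
    latent_activity = pd.Series(latent, index=sample_ids, name="latent_activity")

    # planted gene memberships
    planted = rng.choice(g, size=config.n_up + config.n_down, replace=False)
    membership = np.full(g, "null", dtype=object)
    membership[planted[: config.n_up]] = "up"
    membership[planted[config.n_up:]] = "down"
    membership = pd.Series(membership, index=gene_ids, name="membership")
    sign = membership.map({"up": 1.0, "down": -1.0, "null": 0.0}).to_numpy()

    # expression: log2-mean = baseline_g + s_g * beta * a_i, column-scaled to
    # the target library size, then negative-binomial counts
    baseline = rng.normal(loc=3.0, scale=2.0, size=g)  # log2 of log-normal baselines
    log2_mean = baseline[:, None] + sign[:, None] * config.beta * latent[None, :]
    mean = np.exp2(log2_mean)
    mean *= config.mean_library_size / mean.sum(axis=0, keepdims=True)
    if config.dispersion < 1e-12:
        counts = rng.poisson(mean).astype(float)
    else:
        size = 1.0 / config.dispersion  # NB: var = m + dispersion * m^2
        counts = rng.negative_binomial(size, size / (size + mean)).astype(float)
    expression = ExpressionMatrix(
        data=pd.DataFrame(counts, index=gene_ids, columns=sample_ids), scale="counts"
    )

    # RPPA: anchor = latent + noise; decoys are standard-normal pure noise
    antibody_ids = [ANCHOR_ANTIBODY] + [
        f"DECOY{i + 1}_pX{i + 1}" for i in range(config.n_decoy_antibodies)
    ]
    rppa_values = np.vstack(
        [latent + config.rppa_noise_sd * rng.standard_normal(n)]
        + [rng.standard_normal(n) for _ in range(config.n_decoy_antibodies)]
    )
    rppa = RPPAMatrix(data=pd.DataFrame(rppa_values, index=antibody_ids, columns=sample_ids))

    # clinical covariates: BMI uniform within the class interval; age by
    # menopause status drawn independently of expression
    bmi = np.empty(n)
    for cls, (lo, hi) in _BMI_INTERVALS.items():
        mask = labels == cls
        bmi[mask] = rng.uniform(lo, hi, size=mask.sum())
    pre = rng.random(n) < config.frac_premenopausal
    age = np.where(
        pre,
        rng.integers(config.age_range_pre[0], config.age_range_pre[1] + 1, size=n),
        rng.integers(config.age_range_post[0], config.age_range_post[1] + 1, size=n),
    )
    clinical = ClinicalTable(
        data=pd.DataFrame(
            {"age": age.astype(int), "bmi": bmi, "group": labels}, index=pd.Index(sample_ids)
        )
    )

    truth = SyntheticTruth(
        latent_activity=latent_activity, membership=membership, group=group, config=config
    )
    return SyntheticCohort(expression=expression, rppa=rppa, clinical=clinical, truth=truth)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as TSVs plus a JSON manifest; returns the manifest.

    Files: expression.tsv, rppa.tsv, clinical.tsv, truth.tsv and manifest.json
    (which echoes the configuration). All round-trip losslessly through the
    omics_io readers.
    """
    from . import omics_io  # local import to avoid cycle at module load

    if str(directory) == "":
        raise OSError("empty directory path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    omics_io.write_expression(cohort.expression, directory / "expression.tsv")
    omics_io.write_rppa(cohort.rppa, directory / "rppa.tsv")
    omics_io.write_clinical(cohort.clinical, directory / "clinical.tsv")

    truth = cohort.truth
    truth_rows = pd.concat(
        [
            pd.DataFrame(
                {
                    "entity": "sample",
                    "id": truth.latent_activity.index,
                    "field": "latent_activity",
                    "value": [f"{v:.17g}" for v in truth.latent_activity],
                }
            ),
            pd.DataFrame(
                {
                    "entity": "sample",
                    "id": truth.group.index,
                    "field": "group",
                    "value": truth.group.to_numpy(),
                }
            ),
            pd.DataFrame(
                {
                    "entity": "gene",
                    "id": truth.membership.index,
                    "field": "membership",
                    "value": truth.membership.to_numpy(),
                }
            ),
        ],
        ignore_index=True,
    )
    truth_rows.to_csv(directory / "truth.tsv", sep="\t", index=False)

    manifest = {
        "files": ["expression.tsv", "rppa.tsv", "clinical.tsv", "truth.tsv", "manifest.json"],
        "anchor_antibody": ANCHOR_ANTIBODY,
        "config": cohort.truth.config.to_dict(),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_truth(path: str | Path, config: SimulationConfig) -> SyntheticTruth:
    """Read a truth.tsv written by :func:`write_cohort`."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    lat = df[(df.entity == "sample") & (df.field == "latent_activity")]
    grp = df[(df.entity == "sample") & (df.field == "group")]
    mem = df[(df.entity == "gene") & (df.field == "membership")]
    return SyntheticTruth(
        latent_activity=pd.Series(
            lat.value.astype(float).to_numpy(), index=lat.id.to_numpy(), name="latent_activity"
        ),
        membership=pd.Series(mem.value.to_numpy(), index=mem.id.to_numpy(), name="membership"),
        group=pd.Series(grp.value.to_numpy(), index=grp.id.to_numpy(), name="group"),
        config=config,
    )
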