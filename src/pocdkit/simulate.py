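"""Synthetic cohort generator.

Generates case-control cohorts with the statistical structure the
downstream analysis assumes, so the reliable-change-index classifier and
the genetic association models can be exercised end to end against a
known ground truth:

* genotypes at a biallelic SNP drawn in Hardy-Weinberg proportions at a
  configurable effect-allele (G) frequency;
* a latent binary "surgical insult" whose log-odds depend additively on
  the subject's G-allele count (negative slope = protective allele);
* six correlated test scores per subject at baseline, day 7 and month 3,
  with practice effects shared by patients and controls, and a
  deficit-direction shift applied to insulted patients.

All raw score scales are arbitrary stand-ins (mean 50, residual SD
``noise_sd``): the RCI classification is scale- and shift-invariant, so
only the structure (practice effect, change-score SD, deficit size,
inter-test correlation) matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .battery import BatteryDef, TIMEPOINTS
from .errors import DataError

#: Schema of the cohort CSV (score columns follow, 6 tests x 3 timepoints).
BASE_COLUMNS = ("id", "arm", "genotype", "age", "sex", "education_years")


def _default_practice() -> tuple[float, ...]:
    return (2.0,) * 6


@dataclass
class SimConfig:
    """Generator configuration.

    Defaults mirror the study design the package models: 99 analysable
    surgical patients, 25 age/sex-matched non-surgical controls, a
    G-allele frequency of 0.51 (the pooled patient allele frequency),
    and a protective per-allele log-odds of about -0.9 with an AA
    baseline insult risk near 0.48.

    Parameters
    ----------
    n_patients, n_controls:
        Cohort arm sizes.
    p_g:
        Effect (G) allele frequency in [0, 1]; genotypes are drawn as
        two independent alleles, i.e. Hardy-Weinberg proportions.
    intercept_logit:
        Baseline (genotype AA) log-odds of the latent surgical insult.
    beta_per_g:
        Additive change in insult log-odds per G allele carried
        (negative = protective).
    practice_effect:
        Per-test mean raw-score change per follow-up interval, applied
        identically to both arms (the learning effect the control
        calibration removes).
    decline_magnitude:
        Deficit inflicted on insulted patients, in units of the control
        change-score SD (``noise_sd * sqrt(2)``), applied to every test
        in its deficit direction.
    persistence:
        Probability that an insulted patient's deficit is still present
        at month 3 (partial recovery between day 7 and month 3).
    noise_sd:
        Residual SD of each test score at each timepoint.
    rho:
        Exchangeable correlation of the six tests' noise at a timepoint;
        the 2-of-6 rule's false-positive rate depends on it.
    test_mean:
        Common baseline score mean (arbitrary scale).
    seed:
        Top-level RNG seed; identical config + seed gives a
        bit-identical cohort.
    """

    n_patients: int = 99
    n_controls: int = 25
    p_g: float = 0.51
    intercept_logit: float = -0.095
    beta_per_g: float = -0.9
    practice_effect: tuple[float, ...] = field(default_factory=_default_practice)
    decline_magnitude: float = 2.5
    persistence: float = 0.6
    noise_sd: float = 10.0
    rho: float = 0.3
    test_mean: float = 50.0
    seed: int = 0
    battery: BatteryDef = field(default_factory=BatteryDef.default)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_g <= 1.0:
            raise DataError(f"p_g must be in [0, 1], got {self.p_g}")
        if self.n_patients < 0 or self.n_controls < 0:
            raise DataError("arm sizes must be non-negative")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if not 0.0 <= self.persistence <= 1.0:
            raise DataError("persistence must be in [0, 1]")
        if not -1.0 / (len(self.practice_effect) - 1) < self.rho <= 1.0:
            raise DataError("rho outside the exchangeable-correlation range")
        if len(self.practice_effect) != self.battery.n_tests:
            raise DataError("practice_effect length must match battery size")

    def describe(self) -> dict:
        d = asdict(self)
        d["battery"] = list(self.battery.tests)
        return d


@dataclass
class SubjectRecord:
    """Per-row view of a cohort DataFrame row (one participant)."""

    id: str
    arm: str  # "patient" | "control"
    genotype: int | None  # G-allele count 0/1/2, None when missing
    age: float
    sex: str  # "male" | "female"
    education_years: float
    scores: pd.DataFrame  # index tests, columns TIMEPOINTS
    truth_insult: bool | None = None
    truth_insult_m3: bool | None = None

    @classmethod
    def from_row(cls, row: pd.Series, battery: BatteryDef) -> "SubjectRecord":
        scores = pd.DataFrame(
            {
                tp: [row[battery.score_column(t, tp)] for t in battery.tests]
                for tp in TIMEPOINTS
            },
            index=list(battery.tests),
        )
        g = row["genotype"]
        return cls(
            id=str(row["id"]),
            arm=row["arm"],
            genotype=None if pd.isna(g) else int(g),
            age=float(row["age"]),
            sex=row["sex"],
            education_years=float(row["education_years"]),
            scores=scores,
            truth_insult=row.get("truth_insult"),
            truth_insult_m3=row.get("truth_insult_m3"),
        )


def sample_genotypes(n: int, p_g: float, seed=None) -> np.ndarray:
    """Draw ``n`` G-allele counts, two independent alleles per subject.

    Under random mating this yields Hardy-Weinberg genotype proportions
    (q^2, 2pq, p^2) for (AA, AG, GG) at G frequency ``p_g``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not 0.0 <= p_g <= 1.0:
        raise DataError(f"p_g must be in [0, 1], got {p_g}")
    if n < 0:
        raise DataError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, p_g, size=n)


def _exchangeable_chol(k: int, rho: float, sd: float) -> np.ndarray:
    cov = sd * sd * ((1.0 - rho) * np.eye(k) + rho * np.ones((k, k)))
    return np.linalg.cholesky(cov)


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a cohort DataFrame (one row per subject, cohort CSV schema).

    Controls never receive an insult; each patient's latent insult is
    Bernoulli with logit ``intercept_logit + beta_per_g * g``.  Follow-up
    scores are baseline + practice effect + correlated noise, minus a
    deficit of ``decline_magnitude`` control-change-SDs (in each test's
    deficit direction) for insulted patients; the deficit persists to
    month 3 with probability ``persistence``.  Latent labels are kept in
    ``truth_insult`` / ``truth_insult_m3``.
    """
    rng = np.random.default_rng(config.seed)
    bat = config.battery
    k = bat.n_tests
    n_p, n_c = config.n_patients, config.n_controls
    n = n_p + n_c

    genotype = np.concatenate(
        [
            sample_genotypes(n_p, config.p_g, rng),
            sample_genotypes(n_c, config.p_g, rng),
        ]
    )
    arm = np.array(["patient"] * n_p + ["control"] * n_c)

    # Latent insult: patients only.
    p_insult = expit(config.intercept_logit + config.beta_per_g * genotype[:n_p])
    insult = np.zeros(n, dtype=bool)
    insult[:n_p] = rng.random(n_p) < p_insult
    persists = insult & (
        np.concatenate([rng.random(n_p), np.ones(n_c)]) < config.persistence
    )

    # Decorative demographics (never causal in the generator).
    age = np.round(
        np.concatenate(
            [rng.normal(71.7, 4.5, n_p), rng.normal(68.2, 3.1, n_c)]
        ),
        1,
    )
    sex = np.where(rng.random(n) < 0.8, "male", "female")
    education = np.clip(np.round(rng.normal(4.8, 2.2, n), 1), 0.0, None)

    # Correlated residuals: one k-vector per subject per timepoint.
    chol = _exchangeable_chol(k, config.rho, config.noise_sd)
    eps = rng.standard_normal((n, len(TIMEPOINTS), k)) @ chol.T

    orient = np.asarray(bat.orientation, dtype=float)
    practice = np.asarray(config.practice_effect, dtype=float)
    # Deficit expressed in control change-score SD units; the change-score
    # SD under this noise model is noise_sd * sqrt(2).
    deficit = config.decline_magnitude * config.noise_sd * np.sqrt(2.0)

    baseline = config.test_mean + eps[:, 0, :]
    day7 = baseline + practice + (eps[:, 1, :] - eps[:, 0, :])
    month3 = baseline + practice + (eps[:, 2, :] - eps[:, 0, :])
    day7 -= insult[:, None] * deficit * orient
    month3 -= persists[:, None] * deficit * orient

    data = {
        "id": [f"S{i:04d}" for i in range(n)],
        "arm": arm,
        "genotype": genotype,
        "age": age,
        "sex": sex,
        "education_years": education,
    }
    for tp, mat in zip(TIMEPOINTS, (baseline, day7, month3)):
        for j, t in enumerate(bat.tests):
            data[bat.score_column(t, tp)] = mat[:, j]
    df = pd.DataFrame(data)
    df["truth_insult"] = insult
    df["truth_insult_m3"] = persists
    return df


def write_cohort_csv(cohort: pd.DataFrame, path, include_truth: bool = False) -> None:
    """Write the cohort CSV (UTF-8, header row); truth labels dropped by default."""
    df = cohort if include_truth else cohort.drop(
        columns=[c for c in ("truth_insult", "truth_insult_m3") if c in cohort],
    )
    df.to_csv(path, index=False)


def read_cohort_csv(path, battery: BatteryDef | None = None) -> pd.DataFrame:
    """Read and schema-check a cohort CSV.

    Raises :class:`DataError` naming the offending column or line when the
    schema is violated.
    """
    bat = battery or BatteryDef.default()
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise DataError(f"cohort file not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise DataError(f"cohort file is empty: {path}") from None
    expected = list(BASE_COLUMNS) + [
        bat.score_column(t, tp) for tp in TIMEPOINTS for t in bat.tests
    ]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(f"cohort CSV missing columns: {missing}")
    if len(df) == 0:
        raise DataError(f"cohort file has a header but no subjects: {path}")
    bad_arm = ~df["arm"].isin(["patient", "control"])
    if bad_arm.any():
        line = int(df.index[bad_arm][0]) + 2  # header is line 1
        raise DataError(f"line {line}: arm must be 'patient' or 'control'")
    g = df["genotype"]
    bad_g = g.notna() & ~g.isin([0, 1, 2])
    if bad_g.any():
        line = int(df.index[bad_g][0]) + 2
        raise DataError(f"line {line}: genotype must be 0, 1, 2 or empty")
    return df
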