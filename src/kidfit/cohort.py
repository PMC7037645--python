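"""Seedable synthetic pediatric fitness cohorts.

No raw data accompany the KidFit feasibility study, so every downstream stage
of the analysis is exercised against cohorts simulated here.  The generator
reproduces the published summary structure of the study sample: fifty-seven
children aged 5-17, a male/female split of 34/23, SAMS times around
4.68 +/- 1.40 s, MSTP scores around 21.83 +/- 2.93 laps, measured VO2peak
around 44.12 +/- 11.02 mL/kg/min in a laboratory subset, and widely dispersed
BMI / motor-proficiency percentile ranks.

Cross-measure correlation comes from a single standard-normal latent "fitness"
factor per child.  Each measure loads on that factor with one of two loadings
(a *fitness* loading for the shuttle-test and oxygen-uptake measures, a
*motor* loading for the agility screen, motor-proficiency and adiposity
measures), with signs arranged so that a slower SAMS time co-occurs with a
lower MSTP score, lower VO2peak, lower motor percentile and higher BMI
percentile.  Percentile-scale measures are given moment-matched scaled-Beta
marginals through a Gaussian copula on the same factor: percentile ranks in a
mixed recruitment cohort (obese-enriched plus all-comers) are strongly
over-dispersed relative to a normal, and a Beta marginal reproduces the target
mean and SD exactly while staying inside (0, 100).

The default configuration *is* the study condition; it is not meant to be
tuned per analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .errors import ConfigurationError, InputError

__all__ = [
    "CohortConfig",
    "ChildRecord",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

FEMALE = "female"
MALE = "male"

#: Fixed, documented column order of the cohort CSV.
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "sams_time",
    "mstp_score",
    "vo2peak",
    "bmi_percentile",
    "bot2_total_raw",
    "bot2_gross_raw",
    "bot2_percentile",
]


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults reproduce the KidFit feasibility-study sample (n = 57, with
    laboratory measures of VO2peak and BMI in a 24/57 subset, matching the
    n = 25 lab subset minus the one child whose treadmill test was excluded).
    Loadings are unitless in [0, 1] and control cross-measure correlation;
    the defaults were calibrated once so that the VO2peak ~ SAMS + MSTP
    regression attains R-squared near 0.75 (see docs/methods.md).
    """

    n: int = 57
    age_mean: float = 12.57            # years
    age_sd: float = 1.82
    sex_ratio: float = 34 / 57         # fraction male
    sams_mean: float = 4.68            # seconds
    sams_sd: float = 1.40
    mstp_mean: float = 21.83           # laps
    mstp_sd: float = 2.93
    vo2_mean: float = 44.12            # mL/kg/min (measured VO2peak)
    vo2_sd: float = 11.02
    bmi_pct_mean: float = 51.84        # percentile points
    bmi_pct_sd: float = 33.94
    bot2_pct_mean: float = 61.42
    bot2_pct_sd: float = 30.46
    # BOT2 raw-score moments are nominal (not reported in the study summary);
    # only their correlation structure matters downstream.
    bot2_total_mean: float = 230.0
    bot2_total_sd: float = 35.0
    bot2_gross_mean: float = 110.0
    bot2_gross_sd: float = 20.0
    motor_latent_loading: float = 0.78
    fitness_latent_loading: float = 0.92
    #: Fraction of children with laboratory measures (VO2peak, BMI); the rest
    #: have those fields missing.  24/57 emulates the usable lab subset.
    lab_fraction: float = 24 / 57
    #: Optional additive VO2peak offset (mL/kg/min) for boys, off by default:
    #: the study found no sex differences in raw scores.  Exposed for power
    #: studies only.
    male_vo2_offset: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ConfigurationError(f"n must be an integer >= 1 (got {self.n!r})")
        for field in ("age_sd", "sams_sd", "mstp_sd", "vo2_sd", "bmi_pct_sd",
                      "bot2_pct_sd", "bot2_total_sd", "bot2_gross_sd"):
            v = getattr(self, field)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{field} must be >= 0 (got {v!r})")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError(f"sex_ratio must lie in [0, 1] (got {self.sex_ratio!r})")
        for field in ("motor_latent_loading", "fitness_latent_loading"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{field} must lie in [0, 1] (got {v!r})")
        if not 0.0 <= self.lab_fraction <= 1.0:
            raise ConfigurationError(f"lab_fraction must lie in [0, 1] (got {self.lab_fraction!r})")
        for field in ("bmi_pct", "bot2_pct"):
            mean = getattr(self, f"{field}_mean")
            sd = getattr(self, f"{field}_sd")
            if not 0.0 < mean < 100.0:
                raise ConfigurationError(f"{field}_mean must lie in (0, 100) (got {mean!r})")
            if sd > 0:
                m, v = mean / 100.0, (sd / 100.0) ** 2
                if v >= m * (1 - m):
                    raise ConfigurationError(
                        f"{field}_sd={sd} is too large for a percentile with mean {mean}; "
                        f"sd must be below {100 * math.sqrt(m * (1 - m)):.2f}"
                    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        data = json.loads(text)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown cohort config fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ChildRecord:
    """One participant's raw measures."""

    id: str
    age: float                      # years, in [5, 17]
    sex: str                        # "female" | "male"
    sams_time: float                # seconds, > 0
    mstp_score: float               # laps, multiple of 0.5
    vo2peak: float | None           # mL/kg/min, or None when not lab-measured
    bmi_percentile: float | None    # [0, 100], or None
    bot2_total_raw: float
    bot2_gross_raw: float
    bot2_percentile: float          # [0, 100]

    def validate(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise InputError(f"record {self.id}: sex must be 'female' or 'male' (got {self.sex!r})")
        if not 5.0 <= self.age <= 17.0:
            raise InputError(f"record {self.id}: age {self.age} outside [5, 17]")
        if not self.sams_time > 0:
            raise InputError(f"record {self.id}: sams_time must be > 0 (got {self.sams_time!r})")
        if self.mstp_score < 0 or round(self.mstp_score * 2) != self.mstp_score * 2:
            raise InputError(
                f"record {self.id}: mstp_score must be a nonnegative multiple of 0.5 "
                f"(got {self.mstp_score!r})"
            )
        for name in ("bmi_percentile", "bot2_percentile"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise InputError(f"record {self.id}: {name} {v} outside [0, 100]")


def _beta_params(mean_pct: float, sd_pct: float) -> tuple[float, float]:
    """Shape parameters of a Beta on [0, 1] with the given percentile moments."""
    m, v = mean_pct / 100.0, (sd_pct / 100.0) ** 2
    nu = m * (1 - m) / v - 1
    return m * nu, (1 - m) * nu


def generate_cohort(config: CohortConfig) -> list[ChildRecord]:
    """Generate ``config.n`` children, a deterministic function of the seed.

    Latent structure: one standard-normal factor F per child.  A measure with
    loading ``l`` and sign ``s`` is ``mean + sd * (s*l*F + sqrt(1-l^2)*eps)``
    with independent standard-normal noise ``eps``; percentile measures send
    the same standardized latent score through Phi and then the inverse CDF of
    a moment-matched Beta.  Post-processing: SAMS floored at 2.0 s, MSTP
    rounded to the nearest half lap, percentiles clipped to [0.1, 99.9], ages
    clipped to [5, 17].
    """
    config.validate()
    n = int(config.n)
    rng = np.random.default_rng(config.seed)
    f = rng.standard_normal(n)

    def latent(loading: float, sign: int) -> np.ndarray:
        eps = rng.standard_normal(n)
        return sign * loading * f + math.sqrt(1.0 - loading ** 2) * eps

    def gaussian(mean: float, sd: float, loading: float, sign: int) -> np.ndarray:
        return mean + sd * latent(loading, sign)

    def percentile(mean: float, sd: float, loading: float, sign: int) -> np.ndarray:
        z = latent(loading, sign)
        if sd == 0:
            return np.full(n, mean)
        a, b = _beta_params(mean, sd)
        p = 100.0 * beta_dist.ppf(norm.cdf(z), a, b)
        return np.clip(p, 0.1, 99.9)

    lm, lf = config.motor_latent_loading, config.fitness_latent_loading

    age = np.clip(config.age_mean + config.age_sd * rng.standard_normal(n), 5.0, 17.0)
    male = rng.random(n) < config.sex_ratio
    sams = np.maximum(gaussian(config.sams_mean, config.sams_sd, lm, -1), 2.0)
    mstp = np.maximum(np.round(gaussian(config.mstp_mean, config.mstp_sd, lf, +1) * 2) / 2, 0.0)
    vo2 = np.maximum(
        gaussian(config.vo2_mean, config.vo2_sd, lf, +1) + config.male_vo2_offset * male,
        10.0,
    )
    bmi_pct = percentile(config.bmi_pct_mean, config.bmi_pct_sd, lm, -1)
    bot2_pct = percentile(config.bot2_pct_mean, config.bot2_pct_sd, lm, +1)
    bot2_total = np.maximum(np.round(gaussian(config.bot2_total_mean, config.bot2_total_sd, lm, +1)), 0.0)
    bot2_gross = np.maximum(np.round(gaussian(config.bot2_gross_mean, config.bot2_gross_sd, lm, +1)), 0.0)

    k_lab = int(round(config.lab_fraction * n))
    lab = np.zeros(n, dtype=bool)
    lab[rng.permutation(n)[:k_lab]] = True

    width = max(3, len(str(n)))
    records = []
    for i in range(n):
        records.append(
            ChildRecord(
                id=f"C{i + 1:0{width}d}",
                age=float(age[i]),
                sex=MALE if male[i] else FEMALE,
                sams_time=float(sams[i]),
                mstp_score=float(mstp[i]),
                vo2peak=float(vo2[i]) if lab[i] else None,
                bmi_percentile=float(bmi_pct[i]) if lab[i] else None,
                bot2_total_raw=float(bot2_total[i]),
                bot2_gross_raw=float(bot2_gross[i]),
                bot2_percentile=float(bot2_pct[i]),
            )
        )
    return records


def cohort_to_frame(records: Iterable[ChildRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return frame


def frame_to_records(frame: pd.DataFrame, validate: bool = True) -> list[ChildRecord]:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"cohort table is missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        rec = ChildRecord(
            id=str(row["id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            sams_time=float(row["sams_time"]),
            mstp_score=float(row["mstp_score"]),
            vo2peak=None if pd.isna(row["vo2peak"]) else float(row["vo2peak"]),
            bmi_percentile=None if pd.isna(row["bmi_percentile"]) else float(row["bmi_percentile"]),
            bot2_total_raw=float(row["bot2_total_raw"]),
            bot2_gross_raw=float(row["bot2_gross_raw"]),
            bot2_percentile=float(row["bot2_percentile"]),
        )
        if validate:
            rec.validate()
        records.append(rec)
    return records


def write_cohort_csv(records: Iterable[ChildRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path, validate: bool = True) -> list[ChildRecord]:
    return frame_to_records(pd.read_csv(path), validate=validate)
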