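"""The KidFit decision rule and reference-standard categorizations.

The KidFit Screening Tool combines two field measures:

* **SAMS** (Speed and Agility Motor Screen) — a timed stand/prone/roll/stand/
  jumping-jack sequence; times at or above 5.43 s flag motor concerns.
* **MSTP** (Modified Shuttle Test - Paeds) — a 3-minute 10 m shuttle scored in
  laps (half points for a bean bag in hand); the score feeds a linear
  prediction of VO2max, and predicted values at or below the sex-specific
  cardiorespiratory-fitness cutoffs (34.9 mL/kg/min for girls, 45.1 for boys,
  Cooper Institute reference) flag reduced CRF.

A child is **KidFit positive** when either flag fires.  All boundary
comparisons are inclusive: a SAMS time of exactly 5.43 s and a predicted
VO2max exactly at the cutoff both flag.

The reference-standard categorizations used to judge the screen are also
implemented here: BMI-for-age categories (overweight/obese at or above the
85th percentile, underweight below the 5th), BOT2 motor quartiles (lowest
quartile at percentile rank <= 25), and the six Cooper-Institute CRF bands
(very poor .. superior, with "reduced" meaning very poor/poor/fair).

The MSTP -> VO2max equation is *not* hard-coded: the original study cites it
from earlier work without printing it, so the coefficients are a required
configuration input (``ScreeningRule.vo2_prediction_coefficients``).
``EXAMPLE_VO2_COEFFICIENTS`` ships a moment-implied illustrative equation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .errors import ConfigurationError, InputError

__all__ = [
    "ScreeningRule",
    "KidFitResult",
    "CRFBand",
    "EXAMPLE_VO2_COEFFICIENTS",
    "mstp_score",
    "predict_vo2max_from_mstp",
    "classify_kidfit",
    "crf_band",
    "load_band_table",
    "bmi_category",
    "motor_quartile",
]

#: Illustrative MSTP->VO2max coefficients implied by the study's summary
#: moments (slope = 9.16/2.93 laps-to-mL/kg/min, intercept anchored so an
#: average MSTP score of 21.83 predicts the reported mean 43.63 mL/kg/min).
#: Replace with the published prediction equation for real screening use.
EXAMPLE_VO2_COEFFICIENTS: Mapping[str, float] = {"intercept": -24.617, "mstp": 3.1263}

_SEX_ALIASES = {"f": "female", "female": "female", "m": "male", "male": "male"}


def _norm_sex(sex) -> str:
    try:
        return _SEX_ALIASES[str(sex).strip().lower()]
    except KeyError:
        raise InputError(f"sex must be 'female' or 'male' (got {sex!r})") from None


@dataclass(frozen=True)
class ScreeningRule:
    """KidFit thresholds plus the VO2max prediction coefficients.

    ``vo2_prediction_coefficients`` maps predictor names to coefficients; the
    key ``"intercept"`` is the constant term and ``"mstp"`` multiplies the
    MSTP score.  Any further keys are matched against covariates passed to
    :func:`predict_vo2max_from_mstp`.
    """

    sams_cutoff: float = 5.43            # seconds, inclusive
    vo2_cutoff_female: float = 34.9      # mL/kg/min, inclusive
    vo2_cutoff_male: float = 45.1
    vo2_prediction_coefficients: Mapping[str, float] | None = None

    def __post_init__(self):
        for name in ("sams_cutoff", "vo2_cutoff_female", "vo2_cutoff_male"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0 (got {getattr(self, name)!r})")
        if self.vo2_prediction_coefficients is not None and not self.vo2_prediction_coefficients:
            raise ConfigurationError("vo2_prediction_coefficients must be non-empty when supplied")

    def vo2_cutoff(self, sex) -> float:
        return self.vo2_cutoff_female if _norm_sex(sex) == "female" else self.vo2_cutoff_male


@dataclass(frozen=True)
class KidFitResult:
    child_id: str | None
    sams_flag: bool
    crf_flag: bool

    @property
    def overall(self) -> str:
        """'positive' iff either component flags."""
        return "positive" if (self.sams_flag or self.crf_flag) else "negative"

    @property
    def positive(self) -> bool:
        return self.sams_flag or self.crf_flag


@dataclass(frozen=True)
class CRFBand:
    band: str        # very poor | poor | fair | good | excellent | superior
    reduced: bool    # True iff band in {very poor, poor, fair}


def mstp_score(bags_returned: int, extra_bag_in_hand: bool) -> float:
    """MSTP score in laps: one point per returned bag, half for a bag in hand."""
    if bags_returned < 0:
        raise InputError(f"bags_returned must be >= 0 (got {bags_returned})")
    return float(bags_returned) + (0.5 if extra_bag_in_hand else 0.0)


def predict_vo2max_from_mstp(
    mstp: float,
    rule: ScreeningRule,
    covariates: Mapping[str, float] | None = None,
) -> float:
    """Linear VO2max prediction (mL/kg/min) from the MSTP score.

    Evaluates ``intercept + b_mstp * mstp + sum_k b_k * covariates[k]`` with
    the coefficients carried by ``rule``.
    """
    coeffs = rule.vo2_prediction_coefficients
    if not coeffs:
        raise ConfigurationError(
            "no VO2max prediction coefficients configured: supply the published "
            "MSTP prediction equation (or a custom one) as "
            "ScreeningRule(vo2_prediction_coefficients={'intercept': ..., 'mstp': ...})"
        )
    covariates = dict(covariates or {})
    value = 0.0
    for name, b in coeffs.items():
        if name == "intercept":
            value += b
        elif name == "mstp":
            value += b * mstp
        elif name in covariates:
            value += b * covariates[name]
        else:
            raise InputError(f"prediction coefficient {name!r} has no matching covariate")
    return value


def classify_kidfit(
    sams_time: float,
    predicted_vo2: float,
    sex,
    rule: ScreeningRule | None = None,
    child_id: str | None = None,
) -> KidFitResult:
    """Apply the KidFit positivity rule (both boundaries inclusive)."""
    rule = rule or ScreeningRule()
    if not sams_time > 0:
        raise InputError(f"sams_time must be > 0 (got {sams_time!r})")
    if not math.isfinite(predicted_vo2):
        raise InputError(f"predicted_vo2 must be finite (got {predicted_vo2!r})")
    cutoff = rule.vo2_cutoff(sex)
    return KidFitResult(
        child_id=child_id,
        sams_flag=sams_time >= rule.sams_cutoff,
        crf_flag=predicted_vo2 <= cutoff,
    )


def load_band_table(path=None) -> dict[str, list[tuple[str, float]]]:
    """Load CRF band edges: ``{sex: [(band, inclusive_upper), ...]}`` in order.

    Defaults to the packaged Cooper-Institute-style reference table whose
    fair/good boundaries coincide with the KidFit reduced-CRF cutoffs
    (34.9 female / 45.1 male).
    """
    if path is None:
        source = resources.files("kidfit.data").joinpath("crf_bands.csv").open()
    else:
        source = open(path, newline="")
    table: dict[str, list[tuple[str, float]]] = {}
    with source as fh:
        for row in csv.DictReader(fh):
            table.setdefault(_norm_sex(row["sex"]), []).append(
                (row["band"].strip(), float(row["upper"]))
            )
    for sex, bands in table.items():
        uppers = [u for _, u in bands]
        if sorted(uppers) != uppers:
            raise ConfigurationError(f"band table for {sex} is not sorted by upper edge")
    return table


_REDUCED_BANDS = {"very poor", "poor", "fair"}
_DEFAULT_BANDS: dict[str, list[tuple[str, float]]] | None = None


def crf_band(vo2: float, sex, band_table=None) -> CRFBand:
    """Band a VO2peak value; ``reduced`` is True for very poor / poor / fair."""
    global _DEFAULT_BANDS
    if not vo2 > 0:
        raise InputError(f"vo2 must be > 0 (got {vo2!r})")
    if band_table is None:
        if _DEFAULT_BANDS is None:
            _DEFAULT_BANDS = load_band_table()
        band_table = _DEFAULT_BANDS
    bands = band_table[_norm_sex(sex)]
    for name, upper in bands:
        if vo2 <= upper:
            return CRFBand(band=name, reduced=name in _REDUCED_BANDS)
    return CRFBand(band=bands[-1][0], reduced=bands[-1][0] in _REDUCED_BANDS)


def bmi_category(bmi_percentile: float) -> str:
    """CDC BMI-for-age category from the percentile.

    ``overweight/obese`` at or above the 85th percentile, ``underweight``
    below the 5th, otherwise ``healthy``.
    """
    if not 0.0 <= bmi_percentile <= 100.0:
        raise InputError(f"bmi_percentile {bmi_percentile!r} outside [0, 100]")
    if bmi_percentile >= 85.0:
        return "overweight/obese"
    if bmi_percentile < 5.0:
        return "underweight"
    return "healthy"


def motor_quartile(bot2_percentile: float) -> int:
    """BOT2 motor quartile group: 1 for ranks <= 25 (lowest) up to 4 (> 75)."""
    if not 0.0 <= bot2_percentile <= 100.0:
        raise InputError(f"bot2_percentile {bot2_percentile!r} outside [0, 100]")
    if bot2_percentile <= 25.0:
        return 1
    if bot2_percentile <= 50.0:
        return 2
    if bot2_percentile <= 75.0:
        return 3
    return 4
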