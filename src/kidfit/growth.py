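"""LMS growth-reference transformations (BMI-for-age z-scores and percentiles).

Growth charts tabulate, per sex and age in months, a Box-Cox power L, a
median M and a coefficient of variation S.  A measurement x maps to

    z = ((x/M)^L - 1) / (L*S)     for L != 0
    z = ln(x/M) / S               for L == 0

and the percentile is 100*Phi(z).  Reference rows between tabulated ages are
linearly interpolated in age, per sex.  The reference table itself is
user-supplied CSV (columns ``sex, agemos, L, M, S``); tests use a small
synthetic table, so no chart download is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .errors import InputError

__all__ = ["LMSReferenceRow", "lms_zscore", "lms_percentile", "load_lms_table", "lookup_lms"]

_LMS_COLUMNS = ["sex", "agemos", "L", "M", "S"]


@dataclass(frozen=True)
class LMSReferenceRow:
    sex: str
    agemos: float    # age in months
    L: float         # Box-Cox power (unitless)
    M: float         # median of the measure
    S: float         # coefficient of variation

    def __post_init__(self):
        if not self.M > 0:
            raise InputError(f"LMS row: M must be > 0 (got {self.M!r})")
        if not self.S > 0:
            raise InputError(f"LMS row: S must be > 0 (got {self.S!r})")


def lms_zscore(x: float, row: LMSReferenceRow) -> float:
    """z-score of measurement ``x`` against an LMS reference row.

    For |L| below 1e-7 the power form ((x/M)^L - 1)/(L*S) collapses to 0/0 in
    double precision, so the exact L->0 limit ln(x/M)/S is used instead; the
    two forms agree to ~1e-8 at the switch point.
    """
    if not x > 0:
        raise InputError(f"measurement must be > 0 (got {x!r})")
    if abs(row.L) < 1e-7:
        return math.log(x / row.M) / row.S
    return ((x / row.M) ** row.L - 1.0) / (row.L * row.S)


def lms_percentile(x: float, row: LMSReferenceRow) -> float:
    """Percentile (0-100) of ``x`` under the reference: 100*Phi(z)."""
    return 100.0 * float(norm.cdf(lms_zscore(x, row)))


def load_lms_table(path) -> pd.DataFrame:
    """Read an LMS reference CSV with columns sex, agemos, L, M, S."""
    table = pd.read_csv(path)
    missing = [c for c in _LMS_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"LMS table is missing columns: {missing}")
    if (table["M"] <= 0).any() or (table["S"] <= 0).any():
        raise InputError("LMS table contains nonpositive M or S values")
    return table.sort_values(["sex", "agemos"], kind="stable").reset_index(drop=True)


def lookup_lms(table: pd.DataFrame, sex: str, agemos: float) -> LMSReferenceRow:
    """Reference row at an exact age, linearly interpolating between rows.

    Ages outside the tabulated range use the nearest boundary row.
    """
    sub = table[table["sex"].astype(str).str.lower() == str(sex).lower()]
    if sub.empty:
        raise InputError(f"LMS table has no rows for sex {sex!r}")
    ages = sub["agemos"].to_numpy(float)
    if agemos <= ages[0]:
        r = sub.iloc[0]
        return LMSReferenceRow(str(sex), float(agemos), float(r["L"]), float(r["M"]), float(r["S"]))
    if agemos >= ages[-1]:
        r = sub.iloc[-1]
        return LMSReferenceRow(str(sex), float(agemos), float(r["L"]), float(r["M"]), float(r["S"]))
    import numpy as np

    hi = int(np.searchsorted(ages, agemos, side="left"))
    lo = hi - 1
    if ages[hi] == agemos:
        lo = hi
        w = 0.0
    else:
        w = (agemos - ages[lo]) / (ages[hi] - ages[lo])
    r0, r1 = sub.iloc[lo], sub.iloc[hi]
    return LMSReferenceRow(
        sex=str(sex),
        agemos=float(agemos),
        L=float((1 - w) * r0["L"] + w * r1["L"]),
        M=float((1 - w) * r0["M"] + w * r1["M"]),
        S=float((1 - w) * r0["S"] + w * r1["S"]),
    )
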