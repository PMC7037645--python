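"""Concurrent-validity models: multiple linear regression and t-tests.

The screening tool's components (SAMS time, MSTP score) are entered
simultaneously as predictors of each reference measure (BMI, motor
proficiency raw scores, VO2peak), optionally with age and a 0/1 sex
indicator.  Reported per model: R-squared with the overall-F p-value, and
standardized beta coefficients ``b_j * sd(x_j) / sd(y)`` with their t-test
p-values.  Sex differences in raw measures are assessed with pooled-variance
independent-samples t-tests (df = n1 + n2 - 2).

Missing outcomes or predictors are handled by listwise deletion, so each
model's n follows the available cases (57 for field measures, 24 for the
laboratory subset in the default cohort).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

from .errors import InputError

__all__ = ["RegressionFit", "StandardizedBeta", "TTestResult", "fit_ols", "ttest_independent"]


@dataclass(frozen=True)
class StandardizedBeta:
    beta: float      # coefficient in SD-of-outcome units per SD of predictor
    p_value: float


@dataclass(frozen=True)
class RegressionFit:
    r_squared: float
    model_p: float           # overall F-test p-value
    betas: dict[str, StandardizedBeta]
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float | None          # None when the pooled variance is zero
    df: int
    p: float | None
    mean_difference: float

    @property
    def defined(self) -> bool:
        return self.t is not None


def fit_ols(outcome: Sequence[float], predictors: Mapping[str, Sequence[float]] | pd.DataFrame) -> RegressionFit:
    """Simultaneous-entry least-squares fit with standardized betas.

    Complete cases only; raises when the design is rank deficient, naming the
    offending predictors.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = pd.Series(np.asarray(outcome, dtype=float), index=X.index, name="outcome")
    mask = y.notna() & X.notna().all(axis=1)
    y, X = y[mask], X[mask]
    n, k = len(y), X.shape[1]
    if k == 0:
        raise InputError("at least one predictor is required")
    if n <= k + 1:
        raise InputError(f"too few complete cases (n={n}) for {k} predictors")

    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_columns(design)
        raise InputError(f"design matrix is rank deficient; collinear predictors: {collinear}")

    res = sm.OLS(y, design).fit()
    sd_y = float(y.std(ddof=1))
    if sd_y == 0:
        raise InputError("outcome has zero variance")
    betas = {}
    for name in X.columns:
        b = float(res.params[name])
        betas[name] = StandardizedBeta(
            beta=b * float(X[name].std(ddof=1)) / sd_y,
            p_value=float(res.pvalues[name]),
        )
    return RegressionFit(
        r_squared=float(res.rsquared),
        model_p=float(res.f_pvalue),
        betas=betas,
        n=n,
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Greedy scan for columns that do not increase the design rank."""
    cols: list[str] = []
    offenders: list[str] = []
    current = np.empty((len(design), 0))
    for name in design.columns:
        candidate = np.column_stack([current, design[name].to_numpy(float)])
        if np.linalg.matrix_rank(candidate) > current.shape[1]:
            current = candidate
            cols.append(name)
        else:
            offenders.append(str(name))
    return offenders


def ttest_independent(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sided independent-samples t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise InputError(f"each group needs n >= 2 (got {n1} and {n2})")
    df = n1 + n2 - 2
    diff = float(a.mean() - b.mean())
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=None, df=df, p=None, mean_difference=0.0)
        return TTestResult(t=None, df=df, p=None, mean_difference=diff)
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * float(t_dist.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, mean_difference=diff)
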