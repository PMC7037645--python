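"""Diagnostic-accuracy statistics for a screen judged against a reference state.

Everything needed to fill a screening-validation table from a 2x2 confusion
table is computed here at full precision:

* sensitivity, specificity, PPV, NPV with Wald standard errors
  ``sqrt(p(1-p)/m)`` where m is each estimate's own denominator;
* likelihood ratios LR+ = sens/(1-spec) and LR- = (1-sens)/spec with
  log-method (Simel) confidence intervals,
  ``SE(ln LR+) = sqrt(1/TP - 1/(TP+FN) + 1/FP - 1/(FP+TN))`` and the
  analogous form with FN, TN for LR-;
* the odds ratio with a Woolf (log) interval, applying the Haldane-Anscombe
  continuity correction (add 0.5 to *all four* cells) only when a zero cell
  would otherwise make the OR infinite;
* the efficiency rate (TP+TN)/N — the correct-classification proportion;
* Fisher's exact two-sided p under the point-probability ("minlike")
  convention used by SPSS and R: the sum of hypergeometric probabilities of
  all tables with the observed margins whose probability does not exceed the
  observed table's (ties within a relative tolerance of 1e-7);
* the empirical ROC curve with trapezoidal AUC (equal to the Mann-Whitney
  probability estimate, ties counted 1/2), Hanley-McNeil standard error, a
  Wald 95% interval clipped to [0, 1], and the conventional accuracy band
  (random < 0.5 <= poor < 0.7 <= moderate < 0.9 <= high).

Estimates whose denominator is zero are returned as undefined (``None``)
rather than raising, so one degenerate margin never voids a whole table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom, norm

from .errors import InputError

__all__ = [
    "ConfusionTable",
    "Proportion",
    "RatioEstimate",
    "OddsRatioEstimate",
    "DiagnosticSummary",
    "ROCResult",
    "build_confusion",
    "sens_spec_ppv_npv",
    "likelihood_ratios",
    "odds_ratio",
    "efficiency_rate",
    "fisher_exact",
    "summarize",
    "roc_auc",
]

_FISHER_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FN/FP/TN counts of a screen against a reference state."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InputError(f"{name} must be a nonnegative integer (got {v!r})")
        if self.n < 1:
            raise InputError("confusion table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @property
    def n_screen_positive(self) -> int:
        return self.tp + self.fp

    def has_zero_cell(self) -> bool:
        return min(self.tp, self.fn, self.fp, self.tn) == 0


@dataclass(frozen=True)
class Proportion:
    """A proportion with its Wald standard error; None marks undefined."""

    value: float | None
    se: float | None


@dataclass(frozen=True)
class RatioEstimate:
    """A likelihood ratio with a 95% CI; ci is None when undefined."""

    value: float | None
    ci: tuple[float, float] | None


@dataclass(frozen=True)
class OddsRatioEstimate:
    value: float
    ci: tuple[float, float]
    corrected: bool  # True when the Haldane-Anscombe correction was applied


@dataclass(frozen=True)
class DiagnosticSummary:
    """All table statistics for one screen/state pair."""

    table: ConfusionTable
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    lr_pos: RatioEstimate
    lr_neg: RatioEstimate
    odds_ratio: OddsRatioEstimate
    efficiency_rate: float
    fisher_p: float


@dataclass(frozen=True)
class ROCResult:
    points: tuple[tuple[float, float], ...]  # (1-specificity, sensitivity)
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    band: str  # random | poor | moderate | high


def _as_bool(values: Sequence, true_label: str, false_label: str, what: str) -> np.ndarray:
    out = np.empty(len(values), dtype=bool)
    for i, v in enumerate(values):
        if isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
            continue
        s = str(v).strip().lower()
        if s in (true_label, "+", "1", "true"):
            out[i] = True
        elif s in (false_label, "-", "0", "false"):
            out[i] = False
        else:
            raise InputError(f"unrecognized {what} label {v!r}")
    return out


def build_confusion(screen: Sequence, state: Sequence) -> ConfusionTable:
    """Tally a 2x2 table from parallel screen (+/-) and state labels.

    ``screen`` entries are 'positive'/'negative' (or booleans), ``state``
    entries 'diseased'/'healthy'.  Records with missing state must be
    excluded upstream.
    """
    if len(screen) != len(state):
        raise InputError(f"screen and state differ in length ({len(screen)} vs {len(state)})")
    if len(screen) == 0:
        raise InputError("screen and state must be non-empty")
    s = _as_bool(screen, "positive", "negative", "screen")
    d = _as_bool(state, "diseased", "healthy", "state")
    return ConfusionTable(
        tp=int(np.sum(s & d)),
        fn=int(np.sum(~s & d)),
        fp=int(np.sum(s & ~d)),
        tn=int(np.sum(~s & ~d)),
    )


def _wald(numer: int, denom: int) -> Proportion:
    if denom == 0:
        return Proportion(None, None)
    p = numer / denom
    return Proportion(p, math.sqrt(p * (1 - p) / denom))


def sens_spec_ppv_npv(t: ConfusionTable) -> tuple[Proportion, Proportion, Proportion, Proportion]:
    """Sensitivity, specificity, PPV, NPV; each with its own-denominator Wald SE."""
    return (
        _wald(t.tp, t.tp + t.fn),
        _wald(t.tn, t.tn + t.fp),
        _wald(t.tp, t.tp + t.fp),
        _wald(t.tn, t.tn + t.fn),
    )


def likelihood_ratios(t: ConfusionTable, alpha: float = 0.05) -> tuple[RatioEstimate, RatioEstimate]:
    """LR+ and LR- with log-method CIs.

    LR+ is undefined when specificity = 1 (FP = 0).  When FN = 0, LR- is
    exactly 0 and its CI is reported undefined (the log-method SE involves
    1/FN).  Symmetrically, LR+ with TP = 0 is 0 with an undefined CI.
    """
    z = norm.ppf(1 - alpha / 2)
    sens, spec, _, _ = sens_spec_ppv_npv(t)
    if sens.value is None or spec.value is None:
        return RatioEstimate(None, None), RatioEstimate(None, None)

    if t.fp == 0:
        lr_pos = RatioEstimate(None, None)  # spec = 1: division by zero
    elif t.tp == 0:
        lr_pos = RatioEstimate(0.0, None)
    else:
        value = sens.value / (1 - spec.value)
        se = math.sqrt(1 / t.tp - 1 / t.n_diseased + 1 / t.fp - 1 / t.n_healthy)
        lr_pos = RatioEstimate(
            value, (math.exp(math.log(value) - z * se), math.exp(math.log(value) + z * se))
        )

    if t.tn == 0:
        lr_neg = RatioEstimate(None, None)  # spec = 0: division by zero
    elif t.fn == 0:
        lr_neg = RatioEstimate(0.0, None)
    else:
        value = (1 - sens.value) / spec.value
        se = math.sqrt(1 / t.fn - 1 / t.n_diseased + 1 / t.tn - 1 / t.n_healthy)
        lr_neg = RatioEstimate(
            value, (math.exp(math.log(value) - z * se), math.exp(math.log(value) + z * se))
        )
    return lr_pos, lr_neg


def odds_ratio(t: ConfusionTable, alpha: float = 0.05) -> OddsRatioEstimate:
    """Odds ratio with a Woolf (log) CI; Haldane-Anscombe corrected when needed.

    When any cell is zero, 0.5 is added to all four cells before both the
    point estimate and the interval, which keeps everything finite.
    """
    z = norm.ppf(1 - alpha / 2)
    corrected = t.has_zero_cell()
    c = 0.5 if corrected else 0.0
    a, b, cc, d = t.tp + c, t.fn + c, t.fp + c, t.tn + c
    value = (a * d) / (b * cc)
    se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
    log_or = math.log(value)
    return OddsRatioEstimate(
        value=value,
        ci=(math.exp(log_or - z * se), math.exp(log_or + z * se)),
        corrected=corrected,
    )


def efficiency_rate(t: ConfusionTable) -> float:
    """Correct-classification proportion (TP+TN)/N."""
    return (t.tp + t.tn) / t.n


def fisher_exact(t: ConfusionTable) -> float:
    """Two-sided Fisher exact p (point-probability rule).

    Fixing both margins, the screen-positive diseased count follows a
    hypergeometric law; the p-value sums the probabilities of every table at
    least as extreme (probability <= observed, ties up to rtol 1e-7).
    """
    n_total, k_diseased, n_pos = t.n, t.n_diseased, t.n_screen_positive
    lo = max(0, n_pos - (n_total - k_diseased))
    hi = min(k_diseased, n_pos)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, k_diseased, n_pos)
    p_obs = pmf[support == t.tp][0]
    p = float(np.sum(pmf[pmf <= p_obs * (1 + _FISHER_TIE_RTOL)]))
    return min(p, 1.0)


def summarize(t: ConfusionTable, alpha: float = 0.05) -> DiagnosticSummary:
    """All diagnostic-accuracy statistics for one confusion table."""
    sens, spec, ppv, npv = sens_spec_ppv_npv(t)
    lr_pos, lr_neg = likelihood_ratios(t, alpha=alpha)
    return DiagnosticSummary(
        table=t,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        odds_ratio=odds_ratio(t, alpha=alpha),
        efficiency_rate=efficiency_rate(t),
        fisher_p=fisher_exact(t),
    )


def auc_band(auc: float) -> str:
    """Accuracy band for an AUC; the 0.9 boundary resolves upward to 'high'."""
    if auc < 0.5:
        return "random"
    if auc < 0.7:
        return "poor"
    if auc < 0.9:
        return "moderate"
    return "high"


def roc_auc(
    scores: Sequence[float],
    state: Sequence,
    direction: str = "higher_is_diseased",
) -> ROCResult:
    """Empirical ROC curve and AUC for a continuous score against a state.

    Sweeps every distinct score as a positivity threshold.  The trapezoidal
    AUC over the resulting curve equals the Mann-Whitney estimate
    P(score_diseased > score_healthy) + 0.5 * P(tie).  SE by Hanley-McNeil.
    """
    if direction not in ("higher_is_diseased", "lower_is_diseased"):
        raise InputError(f"unknown direction {direction!r}")
    x = np.asarray(scores, dtype=float)
    d = _as_bool(state, "diseased", "healthy", "state")
    if len(x) != len(d):
        raise InputError(f"scores and state differ in length ({len(x)} vs {len(d)})")
    n1, n0 = int(d.sum()), int((~d).sum())
    if n1 == 0 or n0 == 0:
        raise InputError("state vector must contain both diseased and healthy records")
    if direction == "lower_is_diseased":
        x = -x

    order = np.argsort(-x, kind="stable")
    xs, ds = x[order], d[order]
    # cumulative counts at each distinct threshold (ties grouped)
    boundaries = np.nonzero(np.diff(xs))[0]
    idx = np.concatenate([boundaries, [len(xs) - 1]])
    tp = np.cumsum(ds)[idx]
    fp = np.cumsum(~ds)[idx]
    tpr = np.concatenate([[0.0], tp / n1])
    fpr = np.concatenate([[0.0], fp / n0])
    auc = float(np.trapezoid(tpr, fpr))

    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    z = norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return ROCResult(points=points, auc=auc, auc_se=se, ci95=ci, band=auc_band(auc))
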