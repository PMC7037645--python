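"""Diagnostic-accuracy statistics against hand counts, printed rows and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import mannwhitneyu

from conftest import PRINTED_COUNTS, all_pairs_auc, brute_force_fisher
from kidfit import (
    ConfusionTable,
    InputError,
    build_confusion,
    efficiency_rate,
    fisher_exact,
    likelihood_ratios,
    odds_ratio,
    roc_auc,
    sens_spec_ppv_npv,
    summarize,
)
from kidfit.accuracy import auc_band


# ---------------------------------------------------------------------------
# 2x2 construction
# ---------------------------------------------------------------------------

def test_build_confusion_hand_enumeration():
    t = build_confusion(["positive", "positive", "negative"], ["diseased", "healthy", "healthy"])
    assert (t.tp, t.fn, t.fp, t.tn) == (1, 0, 1, 1)


def test_perfect_screen_has_no_errors():
    state = ["diseased", "healthy", "diseased", "healthy", "healthy"]
    screen = ["positive" if s == "diseased" else "negative" for s in state]
    t = build_confusion(screen, state)
    assert t.fp == t.fn == 0 and t.n == 5


def test_build_confusion_matches_brute_tally():
    rng = np.random.default_rng(0)
    screen = rng.random(200) < 0.4
    state = rng.random(200) < 0.3
    t = build_confusion(screen.tolist(), state.tolist())
    assert t.tp == sum(s and d for s, d in zip(screen, state))
    assert t.fn == sum((not s) and d for s, d in zip(screen, state))
    assert t.fp == sum(s and not d for s, d in zip(screen, state))
    assert t.tn == sum((not s) and (not d) for s, d in zip(screen, state))
    assert t.n == 200


def test_build_confusion_input_errors():
    with pytest.raises(InputError):
        build_confusion(["positive"], ["diseased", "healthy"])
    with pytest.raises(InputError):
        build_confusion([], [])
    with pytest.raises(InputError):
        build_confusion(["maybe"], ["diseased"])


# ---------------------------------------------------------------------------
# proportions and their SEs
# ---------------------------------------------------------------------------

def test_proportions_reproduce_published_motor_row():
    sens, spec, ppv, npv = sens_spec_ppv_npv(ConfusionTable(9, 1, 12, 35))
    assert sens.value == pytest.approx(0.90)
    assert sens.se == pytest.approx(0.095, abs=5e-4)
    assert spec.value == pytest.approx(0.7447, abs=1e-4)
    assert spec.se == pytest.approx(0.064, abs=5e-4)
    assert ppv.value == pytest.approx(0.4286, abs=1e-4)
    assert npv.value == pytest.approx(0.9722, abs=1e-4)
    assert npv.se == pytest.approx(0.027, abs=5e-4)


def test_proportions_zero_error_margins():
    sens, _, _, npv = sens_spec_ppv_npv(ConfusionTable(6, 0, 4, 15))
    assert sens.value == 1.0 and sens.se == 0.0
    assert npv.value == 1.0 and npv.se == 0.0


def test_symmetric_table():
    vals = sens_spec_ppv_npv(ConfusionTable(1, 1, 1, 1))
    for est in vals:
        assert est.value == 0.5
        assert est.se == pytest.approx(math.sqrt(0.25 / 2))


def test_zero_denominator_is_undefined_not_fatal():
    sens, spec, ppv, npv = sens_spec_ppv_npv(ConfusionTable(0, 0, 3, 7))
    assert sens.value is None and sens.se is None
    assert spec.value is not None and npv.value is not None


# ---------------------------------------------------------------------------
# likelihood ratios
# ---------------------------------------------------------------------------

def test_likelihood_ratios_published_motor_row():
    lrp, lrn = likelihood_ratios(ConfusionTable(9, 1, 12, 35))
    assert lrp.value == pytest.approx(3.53, abs=0.01)
    assert lrp.ci[0] == pytest.approx(2.07, abs=0.01)
    assert lrp.ci[1] == pytest.approx(5.99, abs=0.01)
    assert lrn.value == pytest.approx(0.13, abs=0.01)
    assert lrn.ci[0] == pytest.approx(0.02, abs=0.01)
    assert lrn.ci[1] == pytest.approx(0.87, abs=0.01)


def test_lr_neg_zero_false_negatives():
    _, lrn = likelihood_ratios(ConfusionTable(6, 0, 4, 15))
    assert lrn.value == 0.0 and lrn.ci is None


def test_lr_pos_undefined_at_perfect_specificity():
    lrp, _ = likelihood_ratios(ConfusionTable(5, 2, 0, 10))
    assert lrp.value is None and lrp.ci is None


@given(
    tp=st.integers(1, 30), fn=st.integers(1, 30),
    fp=st.integers(1, 30), tn=st.integers(1, 30),
)
def test_lr_direction_when_informative(tp, fn, fp, tn):
    """sens + spec > 1 forces LR+ > 1 and LR- < 1."""
    t = ConfusionTable(tp, fn, fp, tn)
    sens, spec, _, _ = sens_spec_ppv_npv(t)
    if sens.value + spec.value > 1:
        lrp, lrn = likelihood_ratios(t)
        assert lrp.value > 1
        assert lrn.value < 1


# ---------------------------------------------------------------------------
# odds ratio, efficiency rate
# ---------------------------------------------------------------------------

def test_odds_ratio_haldane_corrected_row():
    est = odds_ratio(ConfusionTable(6, 0, 4, 15))
    assert est.corrected
    assert est.value == pytest.approx((6.5 * 15.5) / (0.5 * 4.5), rel=1e-12)
    assert est.value == pytest.approx(44.78, abs=0.005)
    assert est.ci[0] == pytest.approx(2.10, abs=0.01)
    assert est.ci[1] == pytest.approx(956.84, rel=5e-4)


def test_odds_ratio_uncorrected_row():
    est = odds_ratio(ConfusionTable(9, 1, 12, 35))
    assert not est.corrected
    assert est.value == pytest.approx(26.25)
    assert est.ci[0] == pytest.approx(3.00, abs=0.01)
    assert est.ci[1] == pytest.approx(229.34, rel=5e-4)


def test_odds_ratio_null_table():
    est = odds_ratio(ConfusionTable(1, 1, 1, 1))
    assert est.value == pytest.approx(1.0) and not est.corrected


@given(tp=st.integers(1, 20), fn=st.integers(1, 20), fp=st.integers(1, 20), tn=st.integers(1, 20))
def test_or_inverts_under_screen_label_swap(tp, fn, fp, tn):
    """Swapping screen labels (rows) maps OR to 1/OR on uncorrected tables."""
    a = odds_ratio(ConfusionTable(tp, fn, fp, tn))
    b = odds_ratio(ConfusionTable(fn, tp, tn, fp))
    assert a.value * b.value == pytest.approx(1.0)


@pytest.mark.parametrize("counts,expected", [
    ((6, 0, 4, 15), 0.84), ((7, 0, 3, 14), 0.88), ((0, 5, 5, 0), 0.00),
])
def test_efficiency_rate(counts, expected):
    assert round(efficiency_rate(ConfusionTable(*counts)), 2) == expected


@given(tp=st.integers(0, 15), fn=st.integers(0, 15), fp=st.integers(0, 15), tn=st.integers(1, 15))
def test_er_is_prevalence_weighted_accuracy(tp, fn, fp, tn):
    """ER = sens*prevalence + spec*(1-prevalence) exactly, whenever defined."""
    t = ConfusionTable(tp, fn, fp, tn)
    sens, spec, _, _ = sens_spec_ppv_npv(t)
    if sens.value is None or spec.value is None:
        return
    prev = t.n_diseased / t.n
    assert efficiency_rate(t) == pytest.approx(sens.value * prev + spec.value * (1 - prev))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_matches_enumeration_oracle_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(60):
        counts = rng.integers(0, 16, size=4)
        if counts.sum() == 0:
            counts[3] = 1
        t = ConfusionTable(*map(int, counts))
        assert t.n <= 60
        p = fisher_exact(t)
        assert p == pytest.approx(brute_force_fisher(*counts), rel=1e-9)
        # and the library cross-check (same two-sided convention)
        p_sp = scipy_fisher([[t.tp, t.fp], [t.fn, t.tn]], alternative="two-sided")[1]
        assert p == pytest.approx(p_sp, rel=1e-7, abs=1e-12)


def test_fisher_degenerate_margin_is_one():
    assert fisher_exact(ConfusionTable(0, 0, 5, 7)) == 1.0
    assert fisher_exact(ConfusionTable(3, 0, 4, 0)) == 1.0


def test_fisher_invariant_under_transpose():
    rng = np.random.default_rng(9)
    for _ in range(25):
        tp, fn, fp, tn = map(int, rng.integers(0, 12, size=4) + [1, 0, 0, 1])
        p = fisher_exact(ConfusionTable(tp, fn, fp, tn))
        pt = fisher_exact(ConfusionTable(tp, fp, fn, tn))  # transpose 2x2
        assert p == pytest.approx(pt, rel=1e-9)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_perfect_separation():
    r = roc_auc([1, 2, 3, 10, 11, 12], ["healthy"] * 3 + ["diseased"] * 3)
    assert r.auc == pytest.approx(1.0)
    assert r.band == "high"
    assert r.points[0] == (0.0, 0.0) and r.points[-1] == (1.0, 1.0)


def test_auc_equals_all_pairs_oracle_small_samples():
    rng = np.random.default_rng(21)
    for _ in range(40):
        n = int(rng.integers(4, 13))
        d = np.zeros(n, bool)
        d[: int(rng.integers(1, n))] = True
        rng.shuffle(d)
        scores = np.round(rng.normal(size=n) + d, 1)  # induce ties
        state = ["diseased" if x else "healthy" for x in d]
        r = roc_auc(scores.tolist(), state)
        assert r.auc == pytest.approx(all_pairs_auc(scores, d), abs=1e-12)
        u = mannwhitneyu(scores[d], scores[~d]).statistic
        assert r.auc == pytest.approx(u / (d.sum() * (~d).sum()))


def test_auc_negation_duality():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=30)
    d = rng.random(30) < 0.4
    state = ["diseased" if x else "healthy" for x in d]
    a = roc_auc(scores.tolist(), state).auc
    b = roc_auc((-scores).tolist(), state).auc
    assert a + b == pytest.approx(1.0)
    # lower_is_diseased is exactly score negation
    c = roc_auc(scores.tolist(), state, direction="lower_is_diseased").auc
    assert c == pytest.approx(b)


def test_hanley_mcneil_se_formula():
    r = roc_auc([1, 2, 3, 4, 5, 6], ["healthy", "healthy", "diseased", "healthy", "diseased", "diseased"])
    a, n1, n0 = r.auc, 3, 3
    q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    assert r.auc_se == pytest.approx(math.sqrt(var))
    assert r.ci95[0] <= a <= r.ci95[1]
    assert 0.0 <= r.ci95[0] and r.ci95[1] <= 1.0


@pytest.mark.parametrize("auc,band", [
    (0.3, "random"), (0.5, "poor"), (0.69, "poor"), (0.7, "moderate"),
    (0.895, "moderate"), (0.9, "high"), (0.912, "high"), (1.0, "high"),
])
def test_auc_banding(auc, band):
    assert auc_band(auc) == band


def test_roc_rejects_single_class():
    with pytest.raises(InputError):
        roc_auc([1, 2, 3], ["healthy"] * 3)


# ---------------------------------------------------------------------------
# whole-table summaries of the printed rows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("state", list(PRINTED_COUNTS))
def test_summarize_is_internally_consistent(state):
    t = ConfusionTable(*PRINTED_COUNTS[state])
    s = summarize(t)
    assert s.table == t
    if s.lr_pos.ci is not None:
        assert s.lr_pos.ci[0] <= s.lr_pos.value <= s.lr_pos.ci[1]
    assert s.odds_ratio.ci[0] <= s.odds_ratio.value <= s.odds_ratio.ci[1]
    assert 0.0 <= s.efficiency_rate <= 1.0
    assert 0.0 < s.fisher_p <= 1.0
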