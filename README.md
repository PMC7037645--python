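# kidfit

Diagnostic-accuracy analysis of the **KidFit Screening Tool**, a two-component
field screen for identifying children (5–17 y) with health- or motor
performance-related fitness impairments. The package is aimed at pediatric
exercise scientists and biostatisticians who want the full screening-validation
analysis — from cohort to report — as reusable, tested code rather than a
spreadsheet.

## The screen and its evaluation

The KidFit rule combines:

* **SAMS** (Speed and Agility Motor Screen): a timed
  stand → prone → 360° roll → stand → jumping-jack sequence. Times
  **≥ 5.43 s** flag motor concerns.
* **MSTP** (Modified Shuttle Test–Paeds): a 3-minute 10 m shuttle scored in
  laps (half a point for a bean bag in hand). The score feeds a linear
  prediction of VO₂max; predicted values **≤ 34.9 mL·kg⁻¹·min⁻¹ (girls)** or
  **≤ 45.1 (boys)** flag reduced cardiorespiratory fitness.

A child is *KidFit positive* when either flag fires (both boundaries
inclusive). The screen is judged against three reference standards:
BMI-for-age ≥ 85th percentile (overweight/obese), BOT2 motor percentile rank
≤ 25 (lowest motor quartile), and measured VO₂peak in the reduced band of the
Cooper Institute reference.

For a screen vs. state 2×2 table with cells TP/FN/FP/TN the package computes,
at full precision:

* Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV, NPV, each with Wald SE √(p(1−p)/m)
  on its own denominator m;
* LR⁺ = Se/(1−Sp) and LR⁻ = (1−Se)/Sp with log-method CIs,
  SE(ln LR⁺) = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN));
* OR = (TP·TN)/(FN·FP) with a Woolf interval, adding 0.5 to all four cells
  (Haldane–Anscombe) only when a zero cell would make the OR infinite;
* efficiency rate ER = (TP+TN)/N;
* Fisher's exact two-sided p (point-probability convention);
* the empirical ROC curve with trapezoidal AUC (= the Mann–Whitney
  estimate, ties ½), Hanley–McNeil SE, and the conventional accuracy bands
  (random < 0.5 ≤ poor < 0.7 ≤ moderate < 0.9 ≤ high).

Concurrent validity uses simultaneous-entry multiple regression
(R², standardized betas β·sd(x)/sd(y)) and pooled-variance t-tests. Because
no raw data were deposited with the original study, a seedable synthetic
cohort generator (single latent fitness factor, moment-matched marginals)
stands in for the study sample; see `docs/methods.md`.

## Worked example

```python
from kidfit import ConfusionTable, summarize

s = summarize(ConfusionTable(tp=9, fn=1, fp=12, tn=35))  # lowest motor quartile
print(f"Se {100*s.sensitivity.value:.0f}% (SE {s.sensitivity.se:.3f})")
print(f"Sp {100*s.specificity.value:.2f}% (SE {s.specificity.se:.3f})")
print(f"LR+ {s.lr_pos.value:.2f} ({s.lr_pos.ci[0]:.2f}-{s.lr_pos.ci[1]:.2f})")
print(f"OR {s.odds_ratio.value:.2f} ({s.odds_ratio.ci[0]:.2f}-{s.odds_ratio.ci[1]:.2f})")
print(f"ER {s.efficiency_rate:.2f}, Fisher p = {s.fisher_p:.4g}")
```

prints

```
Se 90% (SE 0.095)
Sp 74.47% (SE 0.064)
LR+ 3.52 (2.07-5.99)
OR 26.25 (3.00-229.34)
ER 0.77, Fisher p = 0.0002532
```

i.e. the screen catches 9 of 10 children in the lowest motor quartile, a
positive result multiplies the odds of true impairment 26-fold, and 77% of
children are classified correctly.

Full pipeline from the shell:

```bash
kidfit report --seed 1 --out study_run     # simulate -> classify -> evaluate
kidfit validate                            # recompute the published table
```

`kidfit validate` recomputes every statistic of the original study's
diagnostic table from its printed cell counts and compares cell by cell,
flagging the two cells whose printed values are arithmetically inconsistent
with their own printed counts.

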