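# stopscore

Development and evaluation of the **STOP score** (Sepsis as Trauma Outcome
Prediction) — an additive bedside risk score that identifies severely
injured multiple-trauma patients (ISS ≥ 16) at high risk of developing
sepsis, from four variables measurable within 24 h of admission.

## The score

Each variable contributes points when it crosses a directional cutoff
(all comparisons inclusive):

| variable | cutoff | points |
|---|---|---|
| small (<200 nm) extracellular particles at admission | ≤ 12,639 /μL | 2 |
| leukocyte count on day 1 | ≤ 8.5 ×10³/μL | 2 |
| Injury Severity Score (ISS) | ≥ 25 | 1 |
| packed red blood cells transfused in 24 h | ≥ 1 unit | 1 |

so STOP ∈ {0, …, 6}; a total **> 3** flags the patient as high risk.
The weighting follows a multivariable logistic regression: Wald-significant
predictors (EPs, leukocytes) are double-weighted, the univariately
significant ones (ISS, PRBC) count once.

The package covers the full lifecycle:

* `stopscore.cohort` — patient records, cutoff rules, the score itself
  (missing variables abort scoring; no imputation), CSV/JSON I/O;
* `stopscore.diagnostics` — ROC curves with inclusive thresholds and
  trapezoidal AUC, exact Clopper–Pearson binomial CIs, likelihood ratios,
  2×2 tables, cutoff-selection policies (sensitivity floor / Youden),
  Mann–Whitney U and chi-square screening tests;
* `stopscore.builder` — the development pipeline: category-based
  screening → ROC cutoffs → maximum-likelihood logistic fit (IRLS) →
  Wald-test weighting → score assembly;
* `stopscore.evaluation` — per-score-level PPV stratification and
  threshold metrics with exact CIs;
* `stopscore.simulate` — a synthetic-cohort generator matching the three
  published study groups' summary statistics, plus the deterministic
  124-patient reference cohort.

## Worked example

```python
from stopscore import make_fixture_124, metrics_at_threshold, ppv_by_level
from stopscore.evaluation import levels_to_frame, metrics_to_frame

scores, outcomes, records = make_fixture_124()
print(levels_to_frame(ppv_by_level(scores, outcomes)).to_string(index=False))
print(metrics_to_frame(metrics_at_threshold(scores, outcomes)).to_string(index=False))
```

prints

```
score  n_patients  n_events  ppv_pct  pct_of_cohort
    6           8         6    75.00           6.45
    5           6         3    50.00           4.84
    4          18        10    55.56          14.52
    3          19         5    26.32          15.32
   <3          73         5     6.85          58.87

 threshold      metric  value_pct  ci_lower_pct  ci_upper_pct
         3 sensitivity      65.52         45.67         82.06
         3 specificity      86.32         77.74         92.51
         3         ppv      59.38         40.64         76.30
         3         npv      89.13         80.92         94.66
         3          f1      62.30           NaN           NaN
```

i.e. 75 % of patients scoring 6 developed sepsis, falling to 6.85 % below
3; using "score > 3" as a test, 59.4 % of flagged patients became septic
(sensitivity 65.5 %, specificity 86.3 %, exact 95 % CIs shown).

More narrative scripts live in `examples/` (scoring individual patients,
developing a score on a synthetic cohort, per-marker diagnostic tables).
A thin CLI wraps the same functions:

```bash
stopscore simulate -o cohort.csv --seed 1
stopscore score -i cohort.csv -o scored.csv
stopscore evaluate -i scored.csv -o table.csv
```

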