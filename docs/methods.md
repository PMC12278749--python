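# Methods

## The scoring model

The STOP score is a weighted additive dichotomisation score. Each of four
predictors measurable within 24 h of admission is reduced to a binary
"risk cutoff met" indicator via an inclusive directional threshold, and
the score is the weight-sum of met indicators:

    STOP = 2·1[EP ≤ 12,639/μL] + 2·1[leukocytes_d1 ≤ 8.5×10³/μL]
         + 1·1[ISS ≥ 25] + 1·1[PRBC_24h ≥ 1 unit]   ∈ {0,…,6}

High risk is `STOP > 3` (equivalently ≥ 4). The ">3" reading is fixed by
the published stratified counts: pooling the 8 + 6 + 18 patients at
scores 6/5/4 (6 + 3 + 10 septic) gives PPV 19/32 = 59.4 %, which only the
strict reading reproduces. Boundary comparisons are inclusive, matching
the printed ≤/≥ operators.

Records missing any score variable raise `MissingVariable` instead of
being imputed; the source analysis excluded incomplete rows, and a
bedside score should fail loudly rather than guess.

## Development pipeline

1. **Screening.** Candidate variables are grouped into four clinical
   categories (patient/injury, hemorrhage/coagulation, inflammatory,
   cell-derived). Numeric candidates are tested sepsis-vs-rest with the
   Mann–Whitney U test (midranks for ties; exact two-sided p by
   enumeration when min(n) ≤ 8 without ties, otherwise normal
   approximation with tie and continuity corrections); binary candidates
   with the Pearson chi-square test (no continuity correction). Within a
   category, significant variables (α = 0.05, two-sided throughout, no
   multiplicity correction) are ranked by AUC; the top one enters the
   score, with a manual override hook because clinical accessibility can
   outrank AUC.
2. **Cutoffs.** ROC curves place one operating point per distinct
   observed value (inclusive comparison), plus the two degenerate
   corners; AUC is the trapezoidal area, which equals the tie-corrected
   concordance probability. The default selection policy is a
   *sensitivity floor*: among points with sensitivity ≥ 0.65, maximise
   specificity — a screening-oriented rule preferring high sensitivity
   with adequate specificity; Youden's J is available as an alternative.
   Ties break toward the threshold closest to the median of the curve's
   observed thresholds (the less extreme cutoff); the exact pooled-data
   median with multiplicities is not recoverable from the curve type, and
   with continuous data ties are measure-zero anyway.
3. **Logistic fit.** A multivariable logistic regression is fitted by
   maximum likelihood with Newton/IRLS after listwise deletion.
   Predictors are z-scored internally for conditioning; coefficients are
   reported on both scales and Wald z/p (standard-normal reference, the
   usual ML asymptotics) are computed on the standardized fit, making
   them scale-invariant. Convergence requires the score vector's largest
   component < 1e-8 within 100 iterations; a standardized coefficient
   exceeding 15 in absolute value raises `SeparationError`
   (quasi-complete separation has no finite MLE); a rank-deficient design
   raises `RankDeficient`. A tiny ridge (1e-8) is available purely as a
   numerical fallback for a near-singular information matrix and is
   non-inferential.
4. **Weighting.** Predictors with Wald p < α get weight 2, the rest
   weight 1. Rule order in the assembled definition is normalized to the
   category order (cell-derived, inflammatory, patient/injury,
   hemorrhage/coagulation), so the definition is independent of input
   order.

## Diagnostic statistics

Clopper–Pearson intervals invert the exact binomial tails
(P[X ≥ k | p_lower] = α/2, P[X ≤ k | p_upper] = α/2, with the degenerate
0/1 endpoints at k = 0/n), computed through the beta-quantile closed form
of that inversion; tests verify the tail identity to 1e-8 and agreement
with a bisection-on-tail-sums oracle to 1e-10. The positive likelihood
ratio is sensitivity/(1 − specificity), undefined at specificity 1.

One published anomaly is handled explicitly: in the per-marker tables the
printed "sensitivity" of the sepsis EP row back-calculates to a
proportion of the *no-complication* group (55/79) and the printed
"specificity" to the sepsis group (17/29) — the reverse of the
conventional orientation used for the score-threshold metrics. The
package always computes the conventional orientation; the report helper
`table_row(..., swap_orientation=True)` reproduces the printed
orientation for comparison.

## Synthetic cohorts

No patient-level data are public, so the generator emulates the three
published groups (no complication n=79, pneumonia n=16, sepsis n=29)
from their summary statistics:

* **EP and leukocytes** — lognormal, the natural family for strictly
  positive right-skewed lab values. A two-parameter lognormal cannot
  match both absolute endpoints of an asymmetric printed IQR, so the
  declared contract is: median matched exactly
  (log-location = ln median) and quartile *ratio* matched exactly
  (log-scale = ln(q3/q1)/(2·z₀.₇₅), z₀.₇₅ ≈ 0.6745).
* **ISS** — the same lognormal fit to the printed median/IQR, rounded to
  integers and clipped to [16, 75] (study inclusion required ISS ≥ 16).
  Rounding/truncation shifts the realised quartiles slightly; the printed
  quartiles are treated as the pre-truncation target.
* **PRBC units** — zero-inflated: 0 with probability p_zero, else a
  lognormal draw whose two moments are solved so the *mixture* reproduces
  the printed mean and the SD implied by the printed SEM (sd = sem·√n).
  Only mean ± SEM was published, so p_zero is a modelling assumption
  (0.6 / 0.7 / 0.3 for the three groups): transfusion of ≥ 1 unit must
  be materially more prevalent in the sepsis group to be consistent with
  the printed means. Draws are kept continuous rather than rounded to
  whole units, preserving the exact moment calibration; the score rule
  only asks whether the value reaches 1.
* Every (group, variable) pair consumes an independent substream
  (`SeedSequence([seed, group_index, variable_index])` with append-only
  index tables), so adding or removing a variable never perturbs the
  others at a fixed seed.

The generator draws variables **independently within each group**. Real
trauma data are cross-correlated (e.g. high-ISS patients receive more
transfusions), so passing recovery tests here demonstrate that the
pipeline recovers marginal structure, not that it would reproduce the
original fitted model: in particular, with independent predictors at 10×
the published group sizes *all four* variables become Wald-significant
and the developed score has max weight 8, whereas in the original
124-patient data only EPs and leukocytes were multivariably significant
(max score 6). That difference is a property of the correlation structure
the generator deliberately does not invent, since no correlation matrix
was published.

A second knife-edge consequence of the published summaries: under the
sensitivity-floor policy the selected EP cutoff is the sepsis-group
empirical 0.65-quantile, whose population value (≈ 14,815 particles/μL
for the fitted sepsis lognormal) lies only 0.6 % below the
no-complication generating median (14,904). At 290 sepsis draws the
sampled cutoff therefore lands between the two generating medians only
about half the time; the recovery test that requires all four cutoffs
strictly inside their median bands in ≥ 4/5 fixed seeds documents this
and currently fails on the EP clause (the other three variables and the
weighting clause succeed in 5/5 seeds).

### The 124-patient reference cohort

`make_fixture_124` builds a deterministic cohort whose canonical STOP
scores reproduce the published stratification exactly
(8/6/18/19 patients at scores 6/5/4/3 with 6/3/10/5 septic; 73 below 3
with 5 septic). Each record's variables are set to canonical met/unmet
values realising one documented rule combination per level
(6 = all four; 5 = EP+leuko+ISS; 4 = EP+leuko; 3 = EP+ISS; 2 = leuko;
1 = ISS; 0 = none). Only the pooled "<3" stratum was published, so its
non-septic patients are spread round-robin over scores 0–2 and the five
septic ones placed at score 2 — the aggregate row's PPV (5/73 = 6.85 %)
is invariant to this placement. Non-sepsis outcome labels fill the
published 79/16 no-complication/pneumonia split.

## Numerical and design choices

* Proportions are computed in [0, 1] and rendered as percentages with
  2 decimals in reports.
* ROC AUC uses `(1 − specificity, sensitivity)` trapezoids over the full
  point set; property tests assert exact equality (1e-12) with a
  pair-enumeration concordance oracle on instances up to 12×12,
  including ties.
* The Mann–Whitney and chi-square tests are delegated to scipy behind
  the module interface, with the exact-vs-asymptotic switching rule
  stated above; the logistic IRLS is implemented in the package (its
  convergence rule, separation guard and dual-scale reporting are part
  of the contract) and cross-checked against statsmodels and a
  grid-refinement likelihood maximiser in the tests.
* F1 = 2·PPV·sensitivity/(PPV + sensitivity) is reported without a CI;
  no published value anchors it.
* PPV monotonicity across score levels is *not* asserted anywhere: the
  published table itself is non-monotone (75 %, 50 %, 55.6 %).

## Problem sizes

The default test and acceptance runs use the published cohort (n = 124)
for all deterministic quantities, 10× groups (n = 1,240) for five-seed
pipeline recovery, 100× (n = 12,400) for generator-convergence checks,
500 random instances (≤ 12×12) for the AUC oracle, and 2,000 binomial
draws per (p, n) condition for interval coverage.

## Limitations

* The synthetic generator matches marginal summaries only; no
  between-variable correlation, no time courses, no mortality, no
  pneumonia-specific risk model (the published analysis found the
  pneumonia-associated variables unsuitable for a powered score).
* Per-variable AUCs and sensitivities/specificities of the original
  cohort depend on the unavailable raw data and are not reproduction
  targets; only their arithmetic identities (likelihood ratios, CI
  recomputation from back-calculated counts) are.
* Cutoff transferability is limited: EP quantification is
  cytometer-dependent, so the absolute EP threshold should be
  re-calibrated per centre before any clinical use.
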