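# Methods

## Scores

**GPS.** Two binary abnormalities, CRP > 10 mg/L and albumin < 3.5 g/dL,
summed to 0/1/2. Boundary values (CRP exactly 10, albumin exactly 3.5) are
on the normal side.

**PCPS.** The same construction with prealbumin replacing albumin:
prealbumin < 0.20 mg/dL and CRP ≥ 10 mg/L, summed to 0/1/2. Two boundary
conventions differ deliberately from GPS and from each other:

- *CRP exactly 10* counts as **abnormal** for PCPS but **normal** for GPS.
  Each score follows its own published classification rule; the
  inconsistency is in the definitions themselves, and we preserve it rather
  than silently harmonize.
- *Prealbumin exactly 0.20* is not covered by the published four-row
  classification at all. We treat it as **normal**, mirroring the
  "≥ cut-off is test-negative" convention for a marker whose low values
  flag disease. The choice is a configurable flag
  (`ScoreThresholds.prealbumin_boundary_normal`), and all thresholds
  (0.20, 10, 3.5) are configuration values, not literals, so sensitivity
  analyses are one-line changes.

**Units.** Biomarker units are taken exactly as the reference tables print
them, including prealbumin in "mg/dL" with values 0.14–0.20. Those values
are ~100× below physiological mg/dL prealbumin ranges and are plausibly
g/L mislabeled; the package follows the printed numbers verbatim and does
not guess a conversion. All cut-offs, simulations and results are
internally consistent on the printed scale.

**PG-SGA triage.** The numeric PG-SGA score maps to escalating
intervention bands: 0–1 none needed, 2–3 patient/family education, 4–8
dietitian intervention, ≥ 9 critical need for symptom management and/or
nutritional support. The instrument's internal item scoring is out of
scope; the numeric score and the global A/B/C rating are inputs.

**Missingness.** Scores are never imputed: a missing CRP, albumin or
prealbumin makes the dependent score missing, and every downstream analysis
is complete-case with its effective n recorded. This mirrors the reference
analysis, whose published intervals imply 58 evaluable patients of 71
enrolled.

## Diagnostic evaluation

The positive class is metastatic disease. For a 2×2 table
(tp, fn, fp, tn):

- SEN = tp/(tp+fn), SPE = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn),
  accuracy = (tp+tn)/n, J = SEN+SPE−1, LR⁺ = SEN/(1−SPE),
  LR⁻ = (1−SEN)/SPE.
- **Proportion intervals**: Wilson score method.
- **Likelihood-ratio intervals**: log method,
  ln(LR) ± z·SE with SE(ln LR⁺) = √[(1−SEN)/tp + SPE/fp] and
  SE(ln LR⁻) = √[SEN/fn + (1−SPE)/tn]. A zero cell in an SE term leaves
  the interval undefined and flagged rather than fudged.
- **AUC interval**: Hanley–McNeil, with q₁ = A/(2−A), q₂ = 2A²/(1+A).

The reference publication never names its interval methods. This exact
trio reproduces, under display rounding, all six published intervals of
the prealbumin-cutoff row simultaneously — treated here as a discovered
specification and locked in by tests. No bootstrap or DeLong AUC inference
is provided.

**ROC construction.** Thresholds are the unique observed marker values
plus ±∞ sentinels; for `lower_is_positive` a patient is predicted positive
iff value < threshold. The AUC is the trapezoidal area, which scores tied
positive/negative pairs ½ and therefore equals the Mann-Whitney
U/(n₊·n₋) statistic (property-tested against a brute-force pairwise count
and against an independent AUC implementation). Direction is always an
explicit parameter: prealbumin runs lower-is-positive because the
metastatic group has the lower mean, and auto-detecting direction from the
data would silently flip the test on noisy inputs.

**Youden cut-point.** The threshold maximizing J, with deterministic
tie-breaks: higher sensitivity first, then the lower threshold.

**Decision stump.** The published "regression tree" evaluation of a
3-level ordinal score against a binary outcome is realized as a
single-split Gini stump: every binary split of the ordered levels is
enumerated, the split minimizing weighted Gini impurity wins (ties toward
the lower split level), and each branch predicts its majority outcome
(tied branches predict positive). With one 3-level predictor and a binary
outcome, any deeper tree is vacuous. Resubstitution (apparent) metrics are
reported; whether the original analysis cross-validated is unknown, which
may explain small discrepancies between its stump metrics (n=28-consistent)
and its ROC-row metrics (n=58-consistent). The package reports both
reconstructions without reconciling them.

## Confusion-matrix reconstruction

Published tables print rounded percentages, not counts. `reconstruct`
enumerates every integer table with tp+fn ≤ n_max and tn+fp ≤ n_max
(default n_max = 71, the enrolled cohort size) whose display-rounded
metrics equal the printed ones, for whichever of SEN/SPE/PPV/NPV/accuracy
are supplied. Matching uses half-up rounding to the printed precision
(1 decimal for percentages); a half-even mode exists because the original
rounding rule is unstated — both accept the reference fixtures. Soundness
(every candidate reproduces the inputs) and completeness (a planted table
is always recovered) are property-tested. `verify_against_cis` closes the
loop: the reconstructed table must reproduce the published intervals under
the interval methods above.

## Group comparisons

- Symmetric continuous biomarkers: pooled-variance (Student) two-sample
  t-test with the mean difference oriented nonmetastatic − metastatic and
  a pooled-df 95% CI. Pooled rather than Welch because the published
  mean-difference CIs are consistent with pooled degrees of freedom.
- Skewed variables (CRP, PG-SGA score): two-sided Mann-Whitney, medians
  and quartiles reported.
- Categorical score-by-group tables: Pearson chi-square statistic; the
  "exact" p-value is the exact conditional test — all tables with the
  observed margins, multivariate hypergeometric null, Pearson statistic as
  the ordering criterion (the standard meaning of an exact chi-square in
  mainstream clinical statistics software). Full enumeration when the
  composition bound stays under ~2×10⁶ tables, otherwise Monte Carlo over
  margin-fixed tables with the add-one estimator and an explicit RNG.
- PG-SGA score across score categories: tie-corrected Kruskal-Wallis H.
- No multiple-testing correction is applied, matching the reference
  analysis design.

## Synthetic cohort generator

The generator emulates the marginal structure of the reference cohort; its
defaults are the published summaries and are not tuning knobs:

| parameter | default | source-level meaning |
|---|---|---|
| group sizes | 43 / 28 | metastatic / nonmetastatic counts |
| prealbumin (mg/dL) | N(0.14, 0.06²) / N(0.20, 0.10²) | group mean ± SD |
| albumin (g/dL) | N(3.57, 0.74²) / N(3.94, 0.68²) | |
| transferrin (mg/dL) | N(218.48, 119.68²) / N(279.07, 135.75²) | |
| TLC (10⁹/L) | N(1.18, 0.49²) / N(1.27, 0.54²) | |
| BMI (kg/m²) | N(21.94, 3.94²) / N(22.13, 4.11²) | |
| CRP (mg/L) | log-normal, median (q25–q75) 37.60 (15.59–85.16) / 15.61 (5.52–30.01) | |
| PG-SGA score | log-normal 17 (13–20.5) / 17 (11–19), rounded to integer | |
| sex, site | 79% male, 54% GEJ/proximal | cohort-wide |
| PG-SGA category | A/B/C = 0.13/0.49/0.38 | cohort-wide |
| age | N(62.13, 14.39²), truncated to (18, 100) | cohort-wide |
| missingness | 0.18 per serum biomarker, MCAR | implied evaluable n of 58/71 |

Numerical choices:

- Gaussian biomarkers are truncated at zero by resampling (BMI to its
  physiological range 10–60). For prealbumin the truncation point is
  ~2.3 SD below the mean and shifts the mean by ≈0.0016; for transferrin
  (~1.8 SD) the shift is ≈9 mg/dL, so parameter-recovery tests compare
  sample moments to the truncated distribution's analytic moments.
- CRP and PG-SGA are two-parameter log-normals fitted from the printed
  median and quartiles: μ = ln(median), σ = ln(q75/q25)/(2·z₀.₇₅). This
  matches the median and the quartile *ratio* exactly. The printed CRP
  quartiles are mildly log-asymmetric, so no log-normal can reproduce both
  of them and the median simultaneously; the fitted quartiles land within
  ~3% of the printed ones.
- Biomarkers are sampled independently within group — the source reports
  no covariances. Real biomarker panels are correlated (CRP with albumin
  and prealbumin in particular), so synthetic multivariable results (e.g.
  joint PCPS cell counts) understate real-data dependence; group-wise
  marginal analyses are unaffected. Missingness is MCAR, the mechanism
  being unstated in the source; real missingness is plausibly informative.
- Sex and stage are drawn independently: the published per-sex stage
  breakdown is internally inconsistent (its rows appear swapped), so only
  the overall 43/28 split is modeled.
- Everything is driven by one `numpy` Generator seeded from the config;
  equal (config, seed) gives byte-identical CSV output.

What passing tests show, and don't: recovery of the 0.20 mg/dL cut-off,
the {0,1}-vs-{2} stump split and the direction of the score-by-outcome
association on synthetic data demonstrate that the *methods* behave
correctly under the published marginal structure — not that the published
cohort's patient-level conclusions replicate, which would require real
correlated data.

## Problem sizes

Stochastic checks use sizes at which Monte-Carlo error is comfortably
inside the assertion tolerances: 20,000 patients per group for cut-off
recovery and parameter recovery (cut-off SE ≈ 0.005 against a ±0.02 band),
10⁶ draws for the log-normal quartile oracle, and ≤ 71-per-arm enumeration
(≈ 6.5 M candidate tables before pruning) for reconstruction.

## Known limitations

- No survival analysis: the reference cohort had no follow-up registry.
- No correlated-biomarker or copula generation; no longitudinal
  measurements (single pre-chemotherapy time point).
- Exact conditional p-values are conservative for small tables, as all
  conditional exact tests are; the Monte-Carlo fallback introduces
  resampling error of order 1/√B (B = 9999 by default).
- The reconstruction oracle assumes the published percentages were rounded
  from exact ratios under half-up or half-even rounding; any other
  convention (truncation, sporadic transcription error) would surface as
  an empty candidate set rather than a wrong table.
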