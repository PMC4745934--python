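# pcps

Prognostic scoring and diagnostic evaluation for inoperable gastric
adenocarcinoma cohorts.

Patients with inoperable gastric adenocarcinoma (locally advanced
unresectable stage 3, or metastatic stage 4) carry both a systemic
inflammatory response and a high burden of malnutrition before chemotherapy
begins. The **Glasgow Prognostic Score (GPS)** grades inflammation from CRP
and albumin; the **prealbumin/CRP based prognostic score (PCPS)** replaces
albumin with prealbumin (transthyretin), a visceral protein whose ~2-day
half-life makes it a far more responsive nutritional marker. This package
implements the full analysis workflow around these scores for
biostatisticians and clinical researchers who want to apply, stress-test or
re-derive them without access to patient-level data:

- **Scoring** — GPS and PCPS (0/1/2), PCPS binarization ({0,1} vs {2}),
  and PG-SGA nutritional-triage bands, with explicit boundary conventions
  and strict missingness propagation.
- **Diagnostics** — empirical ROC curves with an explicit test direction,
  Youden-index cut-point selection, and complete 2×2 evaluation:
  SEN/SPE/PPV/NPV/accuracy with Wilson 95% CIs, likelihood ratios with
  log-method (Simel) CIs, AUC with the Hanley–McNeil interval, and a
  Gini-impurity decision stump for ordinal scores.
- **Reconstruction** — a rounding-aware enumeration oracle that recovers
  the exact integer confusion matrices behind published rounded
  percentages.
- **Inference** — pooled-variance t-tests with mean-difference CIs,
  Mann-Whitney, exact conditional chi-square (Pearson ordering), and
  Kruskal-Wallis comparisons.
- **Simulation** — a synthetic cohort generator that emulates the
  reference 71-patient cohort (43 metastatic / 28 nonmetastatic) from its
  published group-wise summaries, including log-normal CRP/PG-SGA fitted
  from median and quartiles and ~18% serum-biomarker missingness.

## The score and its evaluation

For CRP `c` (mg/L), albumin `a` (g/dL) and prealbumin `p` (mg/dL):

    GPS  = [c > 10] + [a < 3.5]          (0, 1 or 2 abnormalities)
    PCPS = [p < 0.20] + [c ≥ 10]

The prealbumin cut-off 0.20 mg/dL is the Youden-optimal ROC threshold
(J = SEN + SPE − 1 maximized, lower prealbumin predicting metastasis). A
binary PCPS test (score 2 = positive) is evaluated against the metastasis
label through the usual operating characteristics, e.g.
LR⁺ = SEN/(1−SPE), with 95% intervals as above.

## Worked example

`python examples/reconstruct_published_table.py` works back from the
published prealbumin-cutoff row (rounded percentages only) to the exact
integer table and re-derives its intervals:

```
published row: SEN 77.1%  SPE 52.2%  PPV 71.1%  NPV 60.0%
candidates within cap: 2; unique minimal: True
minimal table: tp=27 fn=8 fp=11 tn=12 (n=58: 35 metastatic, 23 nonmetastatic)
reproduces all six published 95% CIs: True
recomputed LRs: LR+ 1.61 (published 1.61), LR- 0.44 (published 0.44)

decision-stump metrics (SEN 76.5 / SPE 63.6 / ACC 71.4) -> minimal table (13,4,4,7), n=28
note: the two published metric sets imply different evaluable denominators (28 vs 58); both are reported as found.
```

The four rounded percentages admit exactly one minimal integer table —
27 true positives, 8 false negatives, 11 false positives, 12 true negatives
(58 evaluable patients of the 71 enrolled, the rest lacking a biomarker) —
and that table reproduces every published interval under Wilson / log-method
rounding, which pins down both the reconstruction and the CI methods used.

Other examples: `simulate_cohort.py` (generator vs targets),
`score_and_evaluate.py` (GPS/PCPS scoring and the stump evaluation),
`cutoff_recovery.py` (20k-per-group simulation recovering the 0.20 mg/dL
cut-off; prints AUC 0.713 and a threshold of 0.2023 against the analytic
density crossing 0.2006).

A thin CLI mirrors the library:

```
pcps simulate --seed 42 --out cohort.csv
pcps score cohort.csv --out scored.csv
pcps roc scored.csv --marker prealbumin --direction lower-positive --out roc.json
pcps evaluate scored.csv --predictor pcps_binary --out report.json
pcps reconstruct --sen 77.1 --spe 52.2 --ppv 71.1 --npv 60.0 --out candidates.json
pcps report --seed 42 --out full_report.json
```

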