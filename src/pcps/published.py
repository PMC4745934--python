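"""Printed summary statistics of the reference cohort.

The 71-patient inoperable gastric adenocarcinoma study this package models
published only rounded summary tables, no patient-level data.  Those printed
numbers are the *inputs* to the reconstruction and cross-check machinery:
the ROC operating characteristics and intervals of the prealbumin cut-off
analysis, the decision-tree metrics of the PCPS evaluation, and the
group-wise biomarker summaries (the latter live as the generator defaults
in :mod:`pcps.simulate`).
"""

from __future__ import annotations

COHORT_N = 71
N_METASTATIC = 43
N_NONMETASTATIC = 28

#: PG-SGA global categories A/B/C as printed cohort proportions
PGSGA_CATEGORY_PROPS = (0.13, 0.49, 0.38)

#: prealbumin ROC row: cut-off, AUC and operating characteristics with 95% CIs
ROC_TABLE = {
    "cutoff": 0.20,           # mg/dL, lower values predict metastasis
    "auc": 0.68,
    "ci_auc": (0.54, 0.82),
    "sen_pct": 77.1,
    "spe_pct": 52.2,
    "ppv_pct": 71.1,
    "npv_pct": 60.0,
    "lr_pos": 1.61,
    "lr_neg": 0.44,
    "ci_sen": (61.0, 87.9),
    "ci_spe": (33.0, 70.8),
    "ci_ppv": (55.2, 83.0),
    "ci_npv": (38.7, 78.1),
    "ci_lr_pos": (1.01, 2.56),
    "ci_lr_neg": (0.21, 0.90),
}

#: PCPS decision-stump metrics ({0,1} vs {2} split predicting metastasis)
STUMP_METRICS = {
    "sen_pct": 76.5,
    "spe_pct": 63.6,
    "accuracy_pct": 71.4,
}

#: group-wise mean differences as printed (nonmetastatic minus metastatic)
MEAN_DIFFERENCES = {
    "prealbumin": 0.06,
    "transferrin": 60.59,
}
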