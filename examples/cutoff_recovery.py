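"""Recover the prealbumin cut-off by ROC analysis on simulated data.

Simulates 20,000 patients per outcome group from the group-wise prealbumin
normals (metastatic 0.14 +/- 0.06, nonmetastatic 0.20 +/- 0.10 mg/dL,
truncated at zero), builds the empirical ROC with lower values predicting
metastasis, and maximizes Youden's J = SEN + SPE - 1.  The selected
threshold should land near 0.2006 mg/dL, the analytic crossing point of the
two group densities, matching the 0.20 mg/dL cut-off of the reference
analysis.
"""

import dataclasses

from pcps.diagnostics import roc_curve, youden_cutoff
from pcps.simulate import (METASTATIC_DEFAULTS, NONMETASTATIC_DEFAULTS,
                           default_config, simulate_cohort)

cfg = default_config(
    seed=20_001,
    metastatic=dataclasses.replace(METASTATIC_DEFAULTS, n=20_000),
    nonmetastatic=dataclasses.replace(NONMETASTATIC_DEFAULTS, n=20_000),
    biomarker_missing_rate=0.0,
)
df = simulate_cohort(cfg).to_frame()
curve = roc_curve(df["prealbumin"].to_numpy(float),
                  df["metastatic"].astype(bool).to_numpy(),
                  "lower_is_positive")
cut = youden_cutoff(curve)

print(f"n = {curve.n_pos} metastatic + {curve.n_neg} nonmetastatic")
print(f"AUC = {curve.auc:.3f} "
      f"(95% CI {curve.ci_auc[0]:.3f}-{curve.ci_auc[1]:.3f}, Hanley-McNeil)")
print(f"Youden-optimal cut-off = {cut.threshold:.4f} mg/dL "
      "(analytic density crossing: 0.2006)")
print(f"at the cut-off: SEN {cut.sen:.1%}, SPE {cut.spe:.1%}, J {cut.youden_j:.3f}")
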