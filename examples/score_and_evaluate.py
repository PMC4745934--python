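"""Score a cohort with GPS and PCPS and evaluate PCPS against metastasis.

Scores the default synthetic cohort, fits the single-split decision stump
on the three PCPS levels, and prints the resulting diagnostic report.  The
stump groups scores {0,1} against {2}: patients with both prealbumin and
CRP abnormal are called metastatic.  SEN/SPE/PPV/NPV are percentages with
Wilson 95% intervals; LR+ / LR- are likelihood ratios with log-method
intervals (how strongly a high / low score shifts the odds of metastasis).
"""

from pcps.diagnostics import diagnostic_report, stump_split
from pcps.scoring import score_cohort
from pcps.simulate import default_config, simulate_cohort

df = score_cohort(simulate_cohort(default_config(seed=42)))
complete = df.dropna(subset=["pcps"])
print(f"complete cases with PCPS: {len(complete)} of {len(df)} "
      "(missing biomarkers drop the score)")

truth = complete["metastatic"].astype(bool).to_numpy()
stump = stump_split(complete["pcps"].to_numpy(float), truth)
print(f"Gini-optimal split: PCPS {{0,1}} vs {{>= {stump.split_level:.0f}}} "
      f"(impurity {stump.gini:.3f})")
cm = stump.cm
print(f"confusion matrix: tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")

rd = diagnostic_report(cm).rounded_dict()
for key in ("sen_pct", "spe_pct", "ppv_pct", "npv_pct", "accuracy_pct"):
    ci = rd.get("ci_" + key.removesuffix("_pct"))
    ci_txt = f"  (95% CI {ci[0]}-{ci[1]})" if ci else ""
    print(f"  {key.removesuffix('_pct').upper():<9} {rd[key]:>5}%{ci_txt}")
for key in ("lr_pos", "lr_neg"):
    ci = rd["ci_" + key]
    print(f"  {key.upper():<9} {rd[key]:>5}   (95% CI {ci[0]}-{ci[1]})")
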