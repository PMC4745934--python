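"""Categorical prognostic and nutritional scores.

Two 0/1/2 inflammation-based scores are implemented:

* **GPS** (Glasgow Prognostic Score): CRP > 10 mg/L and albumin < 3.5 g/dL
  each count one abnormality.  Boundary values (CRP exactly 10, albumin
  exactly 3.5) are on the normal side.
* **PCPS** (prealbumin/CRP based prognostic score): prealbumin < 0.20 mg/dL
  and CRP >= 10 mg/L each count one abnormality.  Note the deliberate
  asymmetry with GPS at CRP exactly 10: the PCPS classification table puts
  the boundary on the abnormal side, and each score follows its own printed
  definition.  Prealbumin exactly at the cut-off is treated as normal
  (configurable), mirroring the ">= cut-off is test-negative" convention for
  a marker whose low values flag disease.

Missing inputs are never imputed: a score with a missing input is itself
missing.  PG-SGA triage bands map the numeric PG-SGA score onto escalating
nutritional-intervention needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .cohort import Cohort

__all__ = [
    "ScoreThresholds",
    "DEFAULT_THRESHOLDS",
    "compute_gps",
    "compute_pcps",
    "binarize_pcps",
    "pgsga_triage",
    "score_cohort",
    "TRIAGE_BANDS",
]

TRIAGE_BANDS = (
    "none_needed",                 # PG-SGA 0-1
    "patient_family_education",    # PG-SGA 2-3
    "dietitian_intervention",      # PG-SGA 4-8
    "critical_need",               # PG-SGA >= 9
)


@dataclass(frozen=True)
class ScoreThresholds:
    """Score cut-offs (units: CRP mg/L, albumin g/dL, prealbumin mg/dL)."""

    crp: float = 10.0
    albumin: float = 3.5
    prealbumin: float = 0.20
    #: whether prealbumin exactly at the cut-off counts as normal
    prealbumin_boundary_normal: bool = True


DEFAULT_THRESHOLDS = ScoreThresholds()


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def compute_gps(crp: Optional[float], albumin: Optional[float],
                thresholds: ScoreThresholds = DEFAULT_THRESHOLDS) -> Optional[int]:
    """Glasgow Prognostic Score: number of abnormalities among
    {CRP > 10 mg/L, albumin < 3.5 g/dL}; ``None`` if either input missing."""
    if _is_missing(crp) or _is_missing(albumin):
        return None
    return int(crp > thresholds.crp) + int(albumin < thresholds.albumin)


def compute_pcps(prealbumin: Optional[float], crp: Optional[float],
                 thresholds: ScoreThresholds = DEFAULT_THRESHOLDS) -> Optional[int]:
    """Prealbumin/CRP prognostic score: abnormalities among
    {prealbumin < 0.20 mg/dL, CRP >= 10 mg/L}; ``None`` if an input is missing."""
    if _is_missing(prealbumin) or _is_missing(crp):
        return None
    if thresholds.prealbumin_boundary_normal:
        pre_abnormal = prealbumin < thresholds.prealbumin
    else:
        pre_abnormal = prealbumin <= thresholds.prealbumin
    return int(pre_abnormal) + int(crp >= thresholds.crp)


def binarize_pcps(score: Optional[int]) -> Optional[str]:
    """Collapse PCPS to ``"low"`` (scores 0-1) vs ``"high"`` (score 2)."""
    if score is None:
        return None
    if score not in (0, 1, 2):
        raise ValueError(f"PCPS score must be in {{0,1,2}}, got {score}")
    return "high" if score == 2 else "low"


def pgsga_triage(pgsga_score: Optional[int]) -> Optional[str]:
    """Nutritional-triage band for a scored PG-SGA value."""
    if pgsga_score is None or (isinstance(pgsga_score, float) and math.isnan(pgsga_score)):
        return None
    if pgsga_score < 0:
        raise ValueError("pgsga_score must be >= 0")
    if pgsga_score <= 1:
        return "none_needed"
    if pgsga_score <= 3:
        return "patient_family_education"
    if pgsga_score <= 8:
        return "dietitian_intervention"
    return "critical_need"


def score_cohort(cohort: Union[Cohort, pd.DataFrame],
                 thresholds: ScoreThresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Return the cohort frame augmented with ``gps``, ``pcps``,
    ``pcps_binary`` and ``pgsga_triage`` columns.

    Scores are computed where the inputs are present and left missing
    otherwise; input columns are untouched.  Idempotent: scoring an already
    scored frame recomputes identical columns.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort.copy()
    gps, pcps, binary, triage = [], [], [], []
    for _, row in df.iterrows():
        g = compute_gps(row.get("crp"), row.get("albumin"), thresholds)
        p = compute_pcps(row.get("prealbumin"), row.get("crp"), thresholds)
        s = row.get("pgsga_score")
        gps.append(g)
        pcps.append(p)
        binary.append(binarize_pcps(p))
        triage.append(pgsga_triage(None if pd.isna(s) else int(s)))
    df["gps"] = pd.array(gps, dtype="Int64")
    df["pcps"] = pd.array(pcps, dtype="Int64")
    df["pcps_binary"] = binary
    df["pgsga_triage"] = triage
    return df
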