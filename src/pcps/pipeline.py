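"""End-to-end analysis pipeline.

Simulate (or load) a cohort, score it, run the prealbumin ROC/cut-off
analysis, evaluate the PCPS against the metastasis outcome, and compute the
group-comparison statistics, emitting one machine-readable report whose
sections mirror the standard summary tables of a prognostic-score study:
cohort characteristics, biomarker comparisons by outcome, ROC operating
characteristics, score-by-nutrition and score-by-outcome associations.

Every section records the complete-case n it was computed on — cohorts with
missing biomarkers have different effective denominators per analysis, the
chief reproducibility hazard of this kind of study — and any section whose
preconditions fail is marked skipped with a reason rather than aborting the
rest of the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_cohort
from .diagnostics import (confusion_from_predictions, diagnostic_report,
                          roc_curve, stump_split, youden_cutoff)
from .inference import (compare_categorical, compare_distributions,
                        compare_means, kruskal_wallis)
from .scoring import ScoreThresholds, score_cohort
from .simulate import SyntheticConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

T_TEST_VARIABLES = ("bmi", "albumin", "prealbumin", "transferrin", "tlc")
RANK_VARIABLES = ("crp", "pgsga_score")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Single configuration object driving every pipeline stage."""

    synthetic: SyntheticConfig = SyntheticConfig()
    thresholds: ScoreThresholds = ScoreThresholds()
    roc_marker: str = "prealbumin"
    roc_direction: str = "lower_is_positive"
    conf_level: float = 0.95

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ScoreThresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def _jsonable(obj):
    """Recursively convert report values to plain JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return obj
    return obj


def _cohort_summary(df: pd.DataFrame) -> dict:
    n = len(df)
    cat = df["pgsga_category"].dropna()
    cat_counts = {c: int((cat == c).sum()) for c in ("A", "B", "C")}
    malnourished_pct = 100.0 * (cat_counts["B"] + cat_counts["C"]) / len(cat) if len(cat) else None
    return {
        "n": n,
        "n_metastatic": int(df["metastatic"].sum()),
        "n_nonmetastatic": int((~df["metastatic"].astype(bool)).sum()),
        "pct_male": 100.0 * float((df["sex"] == "male").mean()),
        "pct_gej_proximal": 100.0 * float((df["anatomic_site"] == "GEJ_proximal").mean()),
        "age_mean": float(df["age"].mean()),
        "age_sd": float(df["age"].std(ddof=1)) if n > 1 else None,
        "bmi_mean": float(df["bmi"].mean()),
        "pgsga_mean": float(df["pgsga_score"].mean()),
        "pgsga_sd": float(df["pgsga_score"].std(ddof=1)) if n > 1 else None,
        "pgsga_category_counts": cat_counts,
        "malnourished_pct": malnourished_pct,
    }


def _group_comparisons(df: pd.DataFrame) -> dict:
    out = {}
    truth = df["metastatic"].astype(bool).to_numpy()
    for var in T_TEST_VARIABLES:
        try:
            out[var] = _jsonable(compare_means(df[var].to_numpy(float), truth, variable=var))
        except ValueError as exc:
            out[var] = {"skipped": True, "reason": str(exc)}
    for var in RANK_VARIABLES:
        try:
            out[var] = _jsonable(compare_distributions(df[var].to_numpy(float), truth,
                                                       variable=var))
        except ValueError as exc:
            out[var] = {"skipped": True, "reason": str(exc)}
    return out


def _roc_section(df: pd.DataFrame, config: PipelineConfig) -> dict:
    values = df[config.roc_marker].to_numpy(float)
    truth = df["metastatic"].astype(bool).to_numpy()
    keep = ~np.isnan(values)
    curve = roc_curve(values, truth, direction=config.roc_direction,
                      conf_level=config.conf_level)
    cut = youden_cutoff(curve)
    if config.roc_direction == "lower_is_positive":
        pred = values[keep] < cut.threshold
    else:
        pred = values[keep] > cut.threshold
    cm = confusion_from_predictions(pred, truth[keep])
    report = diagnostic_report(cm, config.conf_level)
    return {
        "marker": config.roc_marker,
        "direction": config.roc_direction,
        "n_complete": int(keep.sum()),
        "auc": curve.auc,
        "ci_auc": list(curve.ci_auc),
        "cutoff": cut.threshold,
        "youden_j": cut.youden_j,
        "evaluation_at_cutoff": _jsonable(report.rounded_dict()),
        "confusion": dataclasses.asdict(cm),
    }


def _pcps_section(df: pd.DataFrame, conf_level: float) -> dict:
    sub = df.dropna(subset=["pcps"])
    truth = sub["metastatic"].astype(bool).to_numpy()
    scores = sub["pcps"].to_numpy(float)
    stump = stump_split(scores, truth)
    report = diagnostic_report(stump.cm, conf_level)
    return {
        "n_complete": int(len(sub)),
        "split_level": stump.split_level,
        "gini": stump.gini,
        "confusion": dataclasses.asdict(stump.cm),
        "evaluation": _jsonable(report.rounded_dict()),
    }


def _crosstab_pct(df: pd.DataFrame, row: str, col: str):
    """Counts and column-percentages of row-category by col-category."""
    sub = df.dropna(subset=[row, col])
    tab = pd.crosstab(sub[row], sub[col])
    pct = (100 * tab / tab.sum(axis=0)).round(1)
    return tab, pct


def _score_by_nutrition(df: pd.DataFrame, rng: np.random.Generator) -> dict:
    out = {}
    for score in ("gps", "pcps"):
        sub = df.dropna(subset=[score, "pgsga_score"])
        try:
            kw = kruskal_wallis(sub["pgsga_score"].to_numpy(float),
                                sub[score].astype(int).to_numpy(), variable=score)
            tab, pct = _crosstab_pct(df, score, "pgsga_category")
            out[score] = {
                "kruskal_wallis": _jsonable(kw),
                "counts": {str(k): v for k, v in tab.to_dict().items()},
                "column_pct": {str(k): v for k, v in pct.to_dict().items()},
                "n_complete": int(len(sub)),
            }
        except ValueError as exc:
            out[score] = {"skipped": True, "reason": str(exc)}
    return out


def _score_by_metastasis(df: pd.DataFrame, rng: np.random.Generator) -> dict:
    out = {}
    for score in ("pgsga_category", "gps", "pcps"):
        sub = df.dropna(subset=[score])
        try:
            tab = pd.crosstab(sub[score], sub["metastatic"].astype(bool))
            comp = compare_categorical(tab.to_numpy(), exact=True, variable=score, rng=rng)
            pct = (100 * tab / tab.sum(axis=0)).round(1)
            out[score] = {
                "test": _jsonable(comp),
                "counts": {str(k): {str(i): int(x) for i, x in v.items()}
                           for k, v in tab.to_dict().items()},
                "column_pct": {str(k): {str(i): float(x) for i, x in v.items()}
                               for k, v in pct.to_dict().items()},
                "n_complete": int(len(sub)),
            }
        except ValueError as exc:
            out[score] = {"skipped": True, "reason": str(exc)}
    return out


def run_pipeline(config: Optional[PipelineConfig] = None,
                 cohort: Optional[Cohort] = None,
                 cohort_path: Optional[Union[str, Path]] = None,
                 seed: Optional[int] = None) -> dict:
    """Run the full analysis and return the report as a JSON-safe dict.

    The cohort is loaded from ``cohort``/``cohort_path`` when given,
    otherwise simulated from ``config.synthetic``.  ``seed`` overrides the
    synthetic seed.  Deterministic given (config, seed).
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config, synthetic=dataclasses.replace(config.synthetic, seed=seed))
    if cohort is None and cohort_path is not None:
        cohort = read_cohort(cohort_path)
    if cohort is None:
        cohort = simulate_cohort(config.synthetic)
    df = score_cohort(cohort, config.thresholds)
    rng = np.random.default_rng(config.synthetic.seed)

    report: dict = {"cohort_summary": _cohort_summary(df)}
    for key, fn in (
        ("group_comparisons", lambda: _group_comparisons(df)),
        ("roc_cutoff", lambda: _roc_section(df, config)),
        ("pcps_evaluation", lambda: _pcps_section(df, config.conf_level)),
        ("score_by_nutrition", lambda: _score_by_nutrition(df, rng)),
        ("score_by_metastasis", lambda: _score_by_metastasis(df, rng)),
    ):
        try:
            report[key] = fn()
        except ValueError as exc:
            report[key] = {"skipped": True, "reason": str(exc)}

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    report["provenance"] = {
        "package_version": __version__,
        "seed": config.synthetic.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "cohort_provenance": _jsonable(cohort.provenance),
        "n_patients": len(cohort),
    }
    return _jsonable(report)


def write_report(report: dict, path: Union[str, Path]) -> None:
    """Serialize a report deterministically (sorted keys, 2-space indent)."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n",
                          encoding="utf-8")
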