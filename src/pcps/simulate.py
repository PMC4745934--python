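"""Synthetic cohort generator for inoperable gastric adenocarcinoma studies.

Emulates the marginal structure of a 71-patient pre-chemotherapy cohort:
two outcome groups (metastatic n=43, nonmetastatic n=28) with group-specific
biomarker distributions, demographic proportions, a right-skewed CRP and
PG-SGA score, and ~18% missingness in the serum biomarkers.

Gaussian biomarkers are drawn from group means/SDs truncated at zero by
resampling (BMI additionally truncated to its physiological range); CRP and
the PG-SGA score, reported in the source cohort as median (25th-75th
percentile), are drawn log-normal with parameters fitted from those
quartiles.  Biomarkers are sampled independently within group — no
correlation structure is modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import Cohort, PatientRecord, AGE_RANGE, BMI_RANGE

__all__ = [
    "GroupParams",
    "SyntheticConfig",
    "fit_lognormal_from_quartiles",
    "simulate_cohort",
    "summarize_cohort",
    "default_config",
    "METASTATIC_DEFAULTS",
    "NONMETASTATIC_DEFAULTS",
]

#: serum biomarkers subject to missingness masking
MASKABLE_BIOMARKERS = ("albumin", "prealbumin", "transferrin", "crp", "tlc")


@dataclass(frozen=True)
class GroupParams:
    """Distributional parameters for one outcome group.

    Gaussian variables are given as (mean, sd); CRP and the PG-SGA score as
    median and 25th/75th percentiles of a log-normal.
    """

    n: int
    prealbumin_mean: float
    prealbumin_sd: float
    albumin_mean: float
    albumin_sd: float
    transferrin_mean: float
    transferrin_sd: float
    tlc_mean: float
    tlc_sd: float
    bmi_mean: float
    bmi_sd: float
    crp_median: float
    crp_q25: float
    crp_q75: float
    pgsga_median: float
    pgsga_q25: float
    pgsga_q75: float

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for name in ("prealbumin", "albumin", "transferrin", "tlc", "bmi"):
            if getattr(self, f"{name}_sd") <= 0:
                raise ValueError(f"{name}_sd must be > 0")
        for name in ("crp", "pgsga"):
            q25, med, q75 = (getattr(self, f"{name}_q25"),
                             getattr(self, f"{name}_median"),
                             getattr(self, f"{name}_q75"))
            if not 0 < q25 < med < q75:
                raise ValueError(f"{name} quartiles must satisfy 0 < q25 < median < q75")


# Group-wise defaults: the metastatic / nonmetastatic biomarker summaries of
# the reference cohort (normal mean±SD; CRP and PG-SGA median and quartiles).
METASTATIC_DEFAULTS = GroupParams(
    n=43,
    prealbumin_mean=0.14, prealbumin_sd=0.06,
    albumin_mean=3.57, albumin_sd=0.74,
    transferrin_mean=218.48, transferrin_sd=119.68,
    tlc_mean=1.18, tlc_sd=0.49,
    bmi_mean=21.94, bmi_sd=3.94,
    crp_median=37.60, crp_q25=15.59, crp_q75=85.16,
    pgsga_median=17.0, pgsga_q25=13.0, pgsga_q75=20.5,
)

NONMETASTATIC_DEFAULTS = GroupParams(
    n=28,
    prealbumin_mean=0.20, prealbumin_sd=0.10,
    albumin_mean=3.94, albumin_sd=0.68,
    transferrin_mean=279.07, transferrin_sd=135.75,
    tlc_mean=1.27, tlc_sd=0.54,
    bmi_mean=22.13, bmi_sd=4.11,
    crp_median=15.61, crp_q25=5.52, crp_q75=30.01,
    pgsga_median=17.0, pgsga_q25=11.0, pgsga_q75=19.0,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; defaults encode the reference cohort."""

    metastatic: GroupParams = METASTATIC_DEFAULTS
    nonmetastatic: GroupParams = NONMETASTATIC_DEFAULTS
    prop_male: float = 0.79
    prop_gej_proximal: float = 0.54
    pgsga_category_probs: Tuple[float, float, float] = (0.13, 0.49, 0.38)
    biomarker_missing_rate: float = 0.18
    age_mean: float = 62.13
    age_sd: float = 14.39
    seed: int = 42

    def validate(self) -> None:
        self.metastatic.validate()
        self.nonmetastatic.validate()
        if self.metastatic.n + self.nonmetastatic.n < 1:
            raise ValueError("total cohort size must be >= 1")
        for name in ("prop_male", "prop_gej_proximal", "biomarker_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        probs = self.pgsga_category_probs
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("pgsga_category_probs must be a 3-vector summing to 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pgsga_category_probs"] = list(self.pgsga_category_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("metastatic", "nonmetastatic"):
            if key in d and isinstance(d[key], dict):
                d[key] = GroupParams(**d[key])
        if "pgsga_category_probs" in d:
            d["pgsga_category_probs"] = tuple(d["pgsga_category_probs"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SyntheticConfig":
        """Load from YAML or JSON (YAML is a JSON superset, so one parser)."""
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_dict(yaml.safe_load(text))


def default_config(seed: int = 42, **overrides) -> SyntheticConfig:
    """The reference-cohort configuration, optionally overridden field-wise."""
    return dataclasses.replace(SyntheticConfig(), seed=seed, **overrides)


def fit_lognormal_from_quartiles(median: float, q25: float, q75: float) -> Tuple[float, float]:
    """Log-normal (mu, sigma) whose median and quartiles match the inputs.

    For X ~ LogNormal(mu, sigma): median = exp(mu) and
    q75/q25 = exp(2 * sigma * z_{0.75}), hence
    mu = ln(median), sigma = ln(q75/q25) / (2 * z_{0.75}) with
    z_{0.75} = Phi^{-1}(0.75) ~= 0.6745.
    """
    if not (0 < q25 < median < q75):
        raise ValueError("require 0 < q25 < median < q75")
    z75 = norm.ppf(0.75)
    return float(np.log(median)), float(np.log(q75 / q25) / (2.0 * z75))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int,
                      low: float = 0.0, high: float = np.inf) -> np.ndarray:
    """Sample N(mean, sd^2) restricted to (low, high) by resampling."""
    out = rng.normal(mean, sd, size=n)
    bad = (out <= low) | (out >= high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= low) | (out >= high)
    return out


def _simulate_group(rng: np.random.Generator, params: GroupParams,
                    config: SyntheticConfig, metastatic: bool,
                    start_index: int) -> list[PatientRecord]:
    n = params.n
    if n == 0:
        return []
    age = _truncated_normal(rng, config.age_mean, config.age_sd, n, *AGE_RANGE)
    bmi = _truncated_normal(rng, params.bmi_mean, params.bmi_sd, n, *BMI_RANGE)
    gaussians = {
        name: _truncated_normal(rng, getattr(params, f"{name}_mean"),
                                getattr(params, f"{name}_sd"), n)
        for name in ("albumin", "prealbumin", "transferrin", "tlc")
    }
    mu, sigma = fit_lognormal_from_quartiles(params.crp_median, params.crp_q25, params.crp_q75)
    crp = rng.lognormal(mu, sigma, size=n)
    mu_p, sigma_p = fit_lognormal_from_quartiles(params.pgsga_median, params.pgsga_q25,
                                                 params.pgsga_q75)
    pgsga = np.rint(rng.lognormal(mu_p, sigma_p, size=n)).astype(int)

    sex = np.where(rng.random(n) < config.prop_male, "male", "female")
    site = np.where(rng.random(n) < config.prop_gej_proximal, "GEJ_proximal", "distal")
    category = rng.choice(np.array(["A", "B", "C"]), size=n,
                          p=np.asarray(config.pgsga_category_probs, dtype=float))

    values = {"bmi": bmi, **gaussians, "crp": crp}
    # independent missingness masks, one per serum biomarker
    masks = {name: rng.random(n) < config.biomarker_missing_rate
             for name in MASKABLE_BIOMARKERS}

    records = []
    for i in range(n):
        def opt(name: str) -> Optional[float]:
            if name in masks and masks[name][i]:
                return None
            return float(values[name][i])

        records.append(PatientRecord(
            patient_id=f"P{start_index + i:04d}",
            age=float(age[i]),
            sex=str(sex[i]),
            anatomic_site=str(site[i]),
            stage=4 if metastatic else 3,
            metastatic=metastatic,
            bmi=float(bmi[i]),
            albumin=opt("albumin"),
            prealbumin=opt("prealbumin"),
            transferrin=opt("transferrin"),
            crp=opt("crp"),
            tlc=opt("tlc"),
            pgsga_score=int(pgsga[i]),
            pgsga_category=str(category[i]),
        ))
    return records


def simulate_cohort(config: Optional[SyntheticConfig] = None) -> Cohort:
    """Draw a synthetic cohort; fully reproducible given ``config.seed``."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    patients = _simulate_group(rng, config.metastatic, config, True, 1)
    patients += _simulate_group(rng, config.nonmetastatic, config, False,
                                1 + config.metastatic.n)
    cohort = Cohort(patients, provenance={
        "source": "synthetic",
        "seed": config.seed,
        "generator": "pcps.simulate",
    })
    cohort.validate()
    return cohort


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Group-wise biomarker summaries over non-missing values.

    One row per (variable, group) with n, mean, sd, median, q25, q75; a group
    with no non-missing values yields NaN summaries (marked unavailable).
    """
    df = cohort.to_frame()
    variables = ["bmi", "albumin", "prealbumin", "transferrin", "crp", "tlc",
                 "pgsga_score"]
    rows = []
    for var in variables:
        for group, label in ((True, "metastatic"), (False, "nonmetastatic")):
            vals = df.loc[df["metastatic"] == group, var].dropna()
            row = {"variable": var, "group": label, "n": int(len(vals))}
            if len(vals) == 0:
                row.update(mean=np.nan, sd=np.nan, median=np.nan,
                           q25=np.nan, q75=np.nan)
            else:
                row.update(
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    median=float(vals.median()),
                    q25=float(vals.quantile(0.25)),
                    q75=float(vals.quantile(0.75)),
                )
            rows.append(row)
    return pd.DataFrame(rows)
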