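"""Binary diagnostic evaluation: ROC curves, Youden cut-points, confusion
matrices, and the confidence-interval methods of classical diagnostic-test
reporting.

The positive class throughout is the metastatic group.  Interval methods are
fixed to the classical trio for this kind of table: Wilson score intervals
for the four proportions (sensitivity, specificity, PPV, NPV), the Simel log
method for likelihood ratios, and the Hanley-McNeil variance for the AUC.

For a biomarker whose *low* values flag disease (prealbumin in a metastatic
group), the ROC direction is ``lower_is_positive``: a patient is predicted
positive when the marker falls strictly below the threshold.  Direction is
always an explicit parameter, never auto-detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from ._rounding import round_pct, round_ratio

__all__ = [
    "ConfusionMatrix",
    "DiagnosticReport",
    "RocCurve",
    "CutoffResult",
    "StumpResult",
    "confusion_from_predictions",
    "diagnostic_report",
    "wilson_interval",
    "roc_curve",
    "hanley_mcneil_ci",
    "youden_cutoff",
    "stump_split",
]

Interval = Tuple[float, float]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts of a binary classifier (positive = metastatic)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class DiagnosticReport:
    """Point estimates and 95% intervals for a 2x2 diagnostic table.

    Proportions are on the 0-1 scale; ``rounded_dict`` applies the table
    display convention (percentages to one decimal, ratios to two,
    half-up).  Likelihood-ratio intervals are ``None`` when a required cell
    is zero (flag recorded in ``flags``).
    """

    sen: float
    spe: float
    ppv: float
    npv: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    youden_j: float
    ci_sen: Interval
    ci_spe: Interval
    ci_ppv: Optional[Interval]
    ci_npv: Optional[Interval]
    ci_lr_pos: Optional[Interval]
    ci_lr_neg: Optional[Interval]
    n_pos: int
    n_neg: int
    conf_level: float = 0.95
    flags: Tuple[str, ...] = ()

    def rounded_dict(self, mode: str = "half_up") -> dict:
        d = {
            "sen_pct": round_pct(100 * self.sen, mode),
            "spe_pct": round_pct(100 * self.spe, mode),
            "ppv_pct": round_pct(100 * self.ppv, mode) if not math.isnan(self.ppv) else None,
            "npv_pct": round_pct(100 * self.npv, mode) if not math.isnan(self.npv) else None,
            "accuracy_pct": round_pct(100 * self.accuracy, mode),
            "lr_pos": round_ratio(self.lr_pos, mode) if math.isfinite(self.lr_pos) else None,
            "lr_neg": round_ratio(self.lr_neg, mode) if math.isfinite(self.lr_neg) else None,
        }
        for name, decimals, scale in (("ci_sen", 1, 100), ("ci_spe", 1, 100),
                                      ("ci_ppv", 1, 100), ("ci_npv", 1, 100),
                                      ("ci_lr_pos", 2, 1), ("ci_lr_neg", 2, 1)):
            ci = getattr(self, name)
            if ci is None:
                d[name] = None
            else:
                rnd = round_pct if decimals == 1 else round_ratio
                d[name] = (rnd(scale * ci[0], mode), rnd(scale * ci[1], mode))
        return d


@dataclass(frozen=True)
class RocCurve:
    """Threshold-indexed ROC operating points with trapezoidal AUC."""

    thresholds: np.ndarray
    sen_at: np.ndarray
    fpr_at: np.ndarray
    direction: str
    auc: float
    ci_auc: Interval
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point of a ROC curve."""

    threshold: float
    youden_j: float
    sen: float
    spe: float


@dataclass(frozen=True)
class StumpResult:
    """Best single binary split of an ordinal score (minimum Gini impurity).

    ``split_level`` is the lowest level of the upper branch: the split is
    {score < split_level} vs {score >= split_level}.  Each branch predicts
    its majority truth class (ties predict positive).
    """

    split_level: float
    gini: float
    cm: ConfusionMatrix
    lower_predicts_positive: bool
    upper_predicts_positive: bool


def confusion_from_predictions(predicted_positive: Sequence[bool],
                               truth: Sequence[bool]) -> ConfusionMatrix:
    """Count the four cells from parallel prediction/truth vectors."""
    pred = np.asarray(predicted_positive, dtype=bool)
    y = np.asarray(truth, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth must have the same length")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fn=int(np.sum(~pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
    )


def wilson_interval(k: int, n: int, conf_level: float = 0.95) -> Interval:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    lo, hi = proportion_confint(k, n, alpha=1 - conf_level, method="wilson")
    return (float(max(0.0, lo)), float(min(1.0, hi)))


def diagnostic_report(cm: ConfusionMatrix, conf_level: float = 0.95) -> DiagnosticReport:
    """Full diagnostic evaluation of a confusion matrix.

    SEN = tp/(tp+fn), SPE = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn),
    accuracy = (tp+tn)/n, LR+ = SEN/(1-SPE), LR- = (1-SEN)/SPE,
    J = SEN + SPE - 1.  Proportion intervals use the Wilson score method;
    LR intervals the log method, ln(LR) +/- z * SE with
    SE(ln LR+) = sqrt((1-SEN)/tp + SPE/fp) and
    SE(ln LR-) = sqrt(SEN/fn + (1-SPE)/tn).
    """
    if cm.n_pos < 1 or cm.n_neg < 1:
        raise ValueError("need at least one positive and one negative case")
    flags: list[str] = []
    sen = cm.tp / cm.n_pos
    spe = cm.tn / cm.n_neg
    ppv = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else math.nan
    npv = cm.tn / (cm.tn + cm.fn) if (cm.tn + cm.fn) > 0 else math.nan
    accuracy = (cm.tp + cm.tn) / cm.n
    lr_pos = sen / (1 - spe) if spe < 1 else math.inf
    lr_neg = (1 - sen) / spe if spe > 0 else math.inf
    z = norm.ppf(0.5 + conf_level / 2)

    ci_sen = wilson_interval(cm.tp, cm.n_pos, conf_level)
    ci_spe = wilson_interval(cm.tn, cm.n_neg, conf_level)
    ci_ppv = wilson_interval(cm.tp, cm.tp + cm.fp, conf_level) if (cm.tp + cm.fp) > 0 else None
    ci_npv = wilson_interval(cm.tn, cm.tn + cm.fn, conf_level) if (cm.tn + cm.fn) > 0 else None

    if math.isfinite(lr_pos) and cm.tp > 0 and cm.fp > 0 and lr_pos > 0:
        se = math.sqrt((1 - sen) / cm.tp + spe / cm.fp)
        ci_lr_pos: Optional[Interval] = (math.exp(math.log(lr_pos) - z * se),
                                         math.exp(math.log(lr_pos) + z * se))
    else:
        ci_lr_pos = None
        flags.append("lr_pos CI undefined (zero cell or perfect specificity)")
    if math.isfinite(lr_neg) and cm.fn > 0 and cm.tn > 0 and lr_neg > 0:
        se = math.sqrt(sen / cm.fn + (1 - spe) / cm.tn)
        ci_lr_neg: Optional[Interval] = (math.exp(math.log(lr_neg) - z * se),
                                         math.exp(math.log(lr_neg) + z * se))
    else:
        ci_lr_neg = None
        flags.append("lr_neg CI undefined (zero cell or perfect sensitivity)")

    return DiagnosticReport(
        sen=sen, spe=spe, ppv=ppv, npv=npv, accuracy=accuracy,
        lr_pos=lr_pos, lr_neg=lr_neg, youden_j=sen + spe - 1,
        ci_sen=ci_sen, ci_spe=ci_spe, ci_ppv=ci_ppv, ci_npv=ci_npv,
        ci_lr_pos=ci_lr_pos, ci_lr_neg=ci_lr_neg,
        n_pos=cm.n_pos, n_neg=cm.n_neg, conf_level=conf_level,
        flags=tuple(flags),
    )


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int,
                     conf_level: float = 0.95) -> Interval:
    """Hanley-McNeil confidence interval for an AUC.

    Uses the variance approximation with q1 = A/(2-A) and
    q2 = 2 A^2 / (1+A):

        Var(A) = [A(1-A) + (n_pos-1)(q1-A^2) + (n_neg-1)(q2-A^2)]
                 / (n_pos * n_neg)
    """
    if not 0 < auc < 1:
        raise ValueError("auc must be strictly between 0 and 1")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 cases per class")
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    z = norm.ppf(0.5 + conf_level / 2)
    half = z * math.sqrt(var)
    return (auc - half, auc + half)


def roc_curve(values: Sequence[float], truth: Sequence[bool],
              direction: str = "lower_is_positive",
              conf_level: float = 0.95) -> RocCurve:
    """Empirical ROC curve of a continuous marker against a binary truth.

    Pairs with a missing marker value are dropped (complete-case).  For
    ``lower_is_positive`` a patient is predicted positive iff value <
    threshold; for ``higher_is_positive`` iff value > threshold.  Thresholds
    are the unique observed values plus sentinels so the curve spans (0,0)
    to (1,1); AUC is the trapezoidal area, which scores tied pairs 1/2,
    and its interval is Hanley-McNeil.
    """
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(truth, dtype=bool)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative complete case")

    pos_sorted = np.sort(v[y])
    neg_sorted = np.sort(v[~y])
    uniq = np.unique(v)
    if direction == "lower_is_positive":
        thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
        # positive iff value < t: counts strictly below each threshold
        sen = np.searchsorted(pos_sorted, thresholds, side="left") / n_pos
        fpr = np.searchsorted(neg_sorted, thresholds, side="left") / n_neg
    else:
        thresholds = np.concatenate(([np.inf], uniq[::-1], [-np.inf]))
        # positive iff value > t: counts strictly above each threshold
        sen = (n_pos - np.searchsorted(pos_sorted, thresholds, side="right")) / n_pos
        fpr = (n_neg - np.searchsorted(neg_sorted, thresholds, side="right")) / n_neg

    auc = float(np.trapezoid(sen, fpr))
    if 0 < auc < 1 and n_pos >= 2 and n_neg >= 2:
        ci = hanley_mcneil_ci(auc, n_pos, n_neg, conf_level)
    else:
        ci = (math.nan, math.nan)
    return RocCurve(thresholds=thresholds, sen_at=sen, fpr_at=fpr,
                    direction=direction, auc=auc, ci_auc=ci,
                    n_pos=n_pos, n_neg=n_neg)


def youden_cutoff(curve: RocCurve) -> CutoffResult:
    """Operating point maximizing Youden's J = SEN + SPE - 1.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold, so the selection is deterministic.
    """
    j = curve.sen_at - curve.fpr_at
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[curve.sen_at[best] >= curve.sen_at[best].max() - 1e-12]
    idx = best[np.argmin(curve.thresholds[best])]
    return CutoffResult(
        threshold=float(curve.thresholds[idx]),
        youden_j=float(j[idx]),
        sen=float(curve.sen_at[idx]),
        spe=float(1 - curve.fpr_at[idx]),
    )


def _gini(counts_pos: int, counts_neg: int) -> float:
    n = counts_pos + counts_neg
    if n == 0:
        return 0.0
    p = counts_pos / n
    return 1.0 - p * p - (1 - p) * (1 - p)


def stump_split(score: Sequence[float], truth: Sequence[bool]) -> StumpResult:
    """Best single split of an ordinal score by weighted Gini impurity.

    Exhaustively evaluates every binary split of the ordered score levels
    ({< level} vs {>= level}); ties in impurity are broken toward the lower
    split level.  Each branch predicts its majority truth class (a tied
    branch predicts positive), and the resulting confusion matrix is
    returned alongside the split.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(truth, dtype=bool)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    levels = np.unique(s)
    if levels.size < 2:
        raise ValueError("score must have at least 2 distinct values")
    n = s.size
    best_gini = math.inf
    best_level = None
    for level in levels[1:]:
        upper = s >= level
        g = ((~upper).sum() / n) * _gini(int(y[~upper].sum()), int((~y[~upper]).sum())) \
            + (upper.sum() / n) * _gini(int(y[upper].sum()), int((~y[upper]).sum()))
        if g < best_gini - 1e-12:
            best_gini = g
            best_level = float(level)
    upper = s >= best_level
    lower_pos = int(y[~upper].sum())
    lower_neg = int((~y[~upper]).sum())
    upper_pos = int(y[upper].sum())
    upper_neg = int((~y[upper]).sum())
    lower_pred = lower_pos >= lower_neg
    upper_pred = upper_pos >= upper_neg
    pred = np.where(upper, upper_pred, lower_pred).astype(bool)
    cm = confusion_from_predictions(pred, y)
    return StumpResult(split_level=best_level, gini=best_gini, cm=cm,
                       lower_predicts_positive=bool(lower_pred),
                       upper_predicts_positive=bool(upper_pred))
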