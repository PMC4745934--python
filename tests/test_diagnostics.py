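"""ROC construction, Youden selection, diagnostic metrics and interval
methods, checked against brute-force oracles and an independent AUC
implementation."""

import math

import numpy as np
import pytest

from pcps.diagnostics import (ConfusionMatrix, confusion_from_predictions,
                              diagnostic_report, hanley_mcneil_ci, roc_curve,
                              stump_split, wilson_interval, youden_cutoff)


def pairwise_auc(values, truth, direction="lower_is_positive"):
    """Brute-force rank oracle: P(positive more extreme than negative),
    ties counted 1/2."""
    v = np.asarray(values, float)
    y = np.asarray(truth, bool)
    pos, neg = v[y], v[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if direction == "lower_is_positive":
                total += 1.0 if p < q else (0.5 if p == q else 0.0)
            else:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------- confusion

def test_confusion_counting():
    assert confusion_from_predictions([1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
                                      [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]) == \
        ConfusionMatrix(5, 0, 0, 5)
    assert confusion_from_predictions([1] * 5, [1, 1, 1, 0, 0]) == \
        ConfusionMatrix(3, 0, 2, 0)
    truth = [True, False, True]
    cm = confusion_from_predictions(truth, truth)
    assert cm.fn == cm.fp == 0


def test_confusion_rejects_empty_and_mismatched():
    with pytest.raises(ValueError):
        confusion_from_predictions([], [])
    with pytest.raises(ValueError):
        confusion_from_predictions([True], [True, False])


# ----------------------------------------------------------- report metrics

def test_report_reproduces_published_operating_characteristics():
    """The 58-patient table (27,8,11,12) yields exactly the published
    prealbumin-cutoff row: SEN 77.1, SPE 52.2, PPV 71.1, NPV 60.0,
    LR+ 1.61, LR- 0.44 and all four Wilson / both log-method intervals."""
    rd = diagnostic_report(ConfusionMatrix(27, 8, 11, 12)).rounded_dict()
    assert rd["sen_pct"] == 77.1
    assert rd["spe_pct"] == 52.2
    assert rd["ppv_pct"] == 71.1
    assert rd["npv_pct"] == 60.0
    assert rd["lr_pos"] == 1.61
    assert rd["lr_neg"] == 0.44
    assert rd["ci_sen"] == (61.0, 87.9)
    assert rd["ci_spe"] == (33.0, 70.8)
    assert rd["ci_ppv"] == (55.2, 83.0)
    assert rd["ci_npv"] == (38.7, 78.1)
    assert rd["ci_lr_pos"] == (1.01, 2.56)
    assert rd["ci_lr_neg"] == (0.21, 0.90)


def test_report_reproduces_published_stump_metrics():
    rd = diagnostic_report(ConfusionMatrix(13, 4, 4, 7)).rounded_dict()
    assert (rd["sen_pct"], rd["spe_pct"], rd["accuracy_pct"]) == (76.5, 63.6, 71.4)


def test_perfect_classifier_report():
    r = diagnostic_report(ConfusionMatrix(4, 0, 0, 4))
    assert r.sen == r.spe == r.ppv == r.npv == r.accuracy == 1.0
    assert r.youden_j == 1.0
    assert math.isinf(r.lr_pos)
    assert r.ci_lr_pos is None and r.flags


def test_report_invariants_on_random_matrices():
    """Exact-arithmetic identities: sen*(tp+fn)=tp, accuracy is the
    prevalence-weighted average of sen and spe, every CI contains its point
    estimate, and J>0 iff LR+>1 iff LR-<1."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        tp, fn, fp, tn = rng.integers(0, 40, size=4)
        if tp + fn == 0 or fp + tn == 0:
            continue
        cm = ConfusionMatrix(int(tp), int(fn), int(fp), int(tn))
        r = diagnostic_report(cm)
        assert round(r.sen * cm.n_pos) == cm.tp
        assert round(r.spe * cm.n_neg) == cm.tn
        assert r.accuracy == pytest.approx(
            (cm.n_pos * r.sen + cm.n_neg * r.spe) / cm.n)
        for point, ci in ((r.sen, r.ci_sen), (r.spe, r.ci_spe)):
            assert ci[0] - 1e-12 <= point <= ci[1] + 1e-12
            assert 0.0 <= ci[0] <= ci[1] <= 1.0
        if math.isfinite(r.lr_pos) and math.isfinite(r.lr_neg) \
                and r.lr_pos > 0 and r.lr_neg > 0:
            assert (r.youden_j > 0) == (r.lr_pos > 1) == (r.lr_neg < 1) \
                or math.isclose(r.youden_j, 0, abs_tol=1e-12)


def test_wilson_zero_count_lower_bound_is_zero():
    lo, hi = wilson_interval(0, 20)
    assert lo == 0.0 and 0 < hi < 1


# ------------------------------------------------------------------- ROC

def test_roc_perfect_separation():
    values = [0.05, 0.06, 0.07, 0.30, 0.31, 0.32]
    truth = [True, True, True, False, False, False]
    curve = roc_curve(values, truth, "lower_is_positive")
    assert curve.auc == 1.0
    cut = youden_cutoff(curve)
    assert cut.youden_j == 1.0
    # tie-break picks the lowest threshold among J-maximal, sen-maximal points
    assert cut.threshold == 0.30


def test_roc_endpoints_and_monotonicity(small_cohort):
    df = small_cohort.to_frame()
    curve = roc_curve(df["prealbumin"], df["metastatic"].astype(bool))
    assert (curve.fpr_at[0], curve.sen_at[0]) == (0.0, 0.0)
    assert (curve.fpr_at[-1], curve.sen_at[-1]) == (1.0, 1.0)
    assert np.all(np.diff(curve.sen_at) >= 0)
    assert np.all(np.diff(curve.fpr_at) >= 0)


@pytest.mark.parametrize("direction", ["lower_is_positive", "higher_is_positive"])
def test_roc_auc_equals_rank_statistic(direction):
    """Trapezoidal AUC equals the pairwise rank statistic U/(n_pos*n_neg)
    with ties counted 1/2, on random instances with heavy ties."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(5, 30))
        values = rng.integers(0, 6, size=n).astype(float)  # many ties
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        curve = roc_curve(values, truth, direction)
        assert curve.auc == pytest.approx(pairwise_auc(values, truth, direction),
                                          abs=1e-12)


def test_roc_auc_equals_sklearn_on_random_data():
    """Independent cross-check against scikit-learn's AUC (negated marker
    maps lower-is-positive onto the standard orientation)."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    values = np.round(rng.normal(0.17, 0.08, size=200), 2)
    truth = rng.random(200) < 0.6
    curve = roc_curve(values, truth, "lower_is_positive")
    assert curve.auc == pytest.approx(roc_auc_score(truth, -values), abs=1e-12)


def test_roc_null_case_auc_near_half():
    rng = np.random.default_rng(11)
    values = rng.normal(size=4000)
    truth = rng.random(4000) < 0.5
    curve = roc_curve(values, truth)
    assert curve.auc == pytest.approx(0.5, abs=0.05)


def test_roc_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    values = rng.lognormal(0, 1, size=100)
    truth = rng.random(100) < 0.4
    a = roc_curve(values, truth, "higher_is_positive").auc
    b = roc_curve(np.log(values), truth, "higher_is_positive").auc
    assert a == pytest.approx(b, abs=1e-12)


def test_roc_rejects_single_class_and_all_missing():
    with pytest.raises(ValueError):
        roc_curve([1.0, 2.0], [True, True])
    with pytest.raises(ValueError):
        roc_curve([math.nan, math.nan], [True, False])


# ------------------------------------------------------------- Hanley-McNeil

def test_hanley_mcneil_reproduces_published_auc_interval():
    lo, hi = hanley_mcneil_ci(0.68, 35, 23)
    assert round(lo, 2) == 0.54
    assert round(hi, 2) == 0.82


def test_hanley_mcneil_symmetry_and_shrinkage():
    lo, hi = hanley_mcneil_ci(0.5, 30, 30)
    assert lo + hi == pytest.approx(1.0)
    widths = [hanley_mcneil_ci(0.7, n, n)[1] - hanley_mcneil_ci(0.7, n, n)[0]
              for n in (10, 20, 40, 80, 160)]
    assert all(a > b for a, b in zip(widths, widths[1:]))


def test_hanley_mcneil_rejects_degenerate():
    with pytest.raises(ValueError):
        hanley_mcneil_ci(1.0, 10, 10)
    with pytest.raises(ValueError):
        hanley_mcneil_ci(0.7, 1, 10)


# ---------------------------------------------------------------- Youden

def test_youden_matches_exhaustive_scan():
    """Exhaustive oracle: max of SEN+SPE-1 over every candidate threshold
    evaluated directly by the prediction rule, on 100 random instances."""
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(6, 25))
        values = np.round(rng.normal(0, 1, size=n), 1)
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        curve = roc_curve(values, truth, "lower_is_positive")
        cut = youden_cutoff(curve)
        pos, neg = values[truth], values[~truth]
        best = -np.inf
        for t in np.concatenate(([-np.inf], np.unique(values), [np.inf])):
            j = np.mean(pos < t) - np.mean(neg < t)
            best = max(best, j)
        assert cut.youden_j == pytest.approx(best, abs=1e-12)
        # the reported operating point is achieved by its own threshold
        assert np.mean(pos < cut.threshold) == pytest.approx(cut.sen)
        assert 1 - np.mean(neg < cut.threshold) == pytest.approx(cut.spe)


# ----------------------------------------------------------------- stump

def gini_oracle(score, truth, level):
    s, y = np.asarray(score, float), np.asarray(truth, bool)
    upper = s >= level
    out = 0.0
    for side in (upper, ~upper):
        if side.sum() == 0:
            continue
        p = y[side].mean()
        out += side.mean() * (1 - p * p - (1 - p) * (1 - p))
    return out


def test_stump_matches_enumeration_oracle():
    rng = np.random.default_rng(21)
    for _ in range(60):
        n = int(rng.integers(8, 40))
        score = rng.integers(0, 4, size=n).astype(float)
        truth = rng.random(n) < 0.5
        if len(np.unique(score)) < 2:
            continue
        res = stump_split(score, truth)
        ginis = [gini_oracle(score, truth, lv) for lv in np.unique(score)[1:]]
        assert res.gini == pytest.approx(min(ginis), abs=1e-12)


def test_stump_on_score_2_enriched_cohort_selects_published_grouping():
    """When PCPS level 2 is metastasis-enriched (as in the reference
    score-by-outcome distribution: 76% of metastatic vs 36% of
    nonmetastatic patients at score 2), the Gini-optimal split is
    {0,1} vs {2}."""
    rng = np.random.default_rng(4)
    n_met, n_non = 200, 130
    met = rng.choice([0, 1, 2], size=n_met, p=[0.09, 0.15, 0.76])
    non = rng.choice([0, 1, 2], size=n_non, p=[0.27, 0.37, 0.36])
    score = np.concatenate([met, non]).astype(float)
    truth = np.concatenate([np.ones(n_met, bool), np.zeros(n_non, bool)])
    res = stump_split(score, truth)
    assert res.split_level == 2.0
    assert res.upper_predicts_positive and not res.lower_predicts_positive


def test_stump_perfect_binary_score():
    res = stump_split([0, 0, 1, 1], [False, False, True, True])
    assert res.gini == 0.0
    assert res.cm == ConfusionMatrix(2, 0, 0, 2)


def test_stump_rejects_single_level():
    with pytest.raises(ValueError):
        stump_split([1, 1, 1], [True, False, True])
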