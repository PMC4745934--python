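"""Group-comparison statistics for biomarker cohorts.

Continuous biomarkers with roughly symmetric distributions are compared by
the pooled-variance two-sample t-test with a 95% CI on the mean difference
(oriented nonmetastatic minus metastatic, so that positive differences
favour the nonmetastatic group); skewed variables (CRP, PG-SGA score) by the
Mann-Whitney rank-sum test; categorical score distributions by the Pearson
chi-square statistic with an exact conditional p-value; and the association
of a numeric score across >= 2 categories by the Kruskal-Wallis H test.

The exact conditional chi-square test enumerates all tables with the
observed margins (multivariate hypergeometric null) and sums the
probability of tables whose Pearson statistic is at least the observed one;
for tables too large to enumerate it falls back to Monte Carlo sampling of
margin-fixed tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_means",
    "compare_distributions",
    "compare_categorical",
    "kruskal_wallis",
    "exact_chi_square_p",
]

Interval = Tuple[float, float]


@dataclass(frozen=True)
class GroupComparison:
    """Result of one group-comparison test."""

    variable: str
    method: str
    statistic: float
    p_value: float
    mean_diff: Optional[float] = None
    mean_diff_ci: Optional[Interval] = None
    group_summaries: dict = field(default_factory=dict)
    n: Optional[int] = None


def _complete_pairs(values: Sequence[float], group: Sequence[bool]):
    v = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=bool)
    keep = ~np.isnan(v)
    return v[keep], g[keep]


def compare_means(values: Sequence[float], group: Sequence[bool],
                  variable: str = "", conf_level: float = 0.95) -> GroupComparison:
    """Pooled-variance two-sample t-test.

    ``group`` is the metastatic indicator; the reported difference is
    mean(nonmetastatic) - mean(metastatic) with its pooled-df CI.
    """
    v, g = _complete_pairs(values, group)
    a, b = v[~g], v[g]  # nonmetastatic, metastatic
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 complete cases per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    ci = res.confidence_interval(conf_level)
    return GroupComparison(
        variable=variable, method="t_test",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
        mean_diff_ci=(float(ci.low), float(ci.high)),
        group_summaries={
            "nonmetastatic": {"n": int(len(a)), "mean": float(a.mean()),
                              "sd": float(a.std(ddof=1))},
            "metastatic": {"n": int(len(b)), "mean": float(b.mean()),
                           "sd": float(b.std(ddof=1))},
        },
        n=int(len(v)),
    )


def compare_distributions(values: Sequence[float], group: Sequence[bool],
                          variable: str = "", method: str = "auto",
                          continuity: bool = True) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum test; reports medians and quartiles."""
    v, g = _complete_pairs(values, group)
    a, b = v[~g], v[g]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("need >= 1 complete case per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=continuity)

    def summ(x: np.ndarray) -> dict:
        return {"n": int(len(x)), "median": float(np.median(x)),
                "q25": float(np.percentile(x, 25)), "q75": float(np.percentile(x, 75))}

    return GroupComparison(
        variable=variable, method="mann_whitney",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        group_summaries={"nonmetastatic": summ(a), "metastatic": summ(b)},
        n=int(len(v)),
    )


def _pearson_chi2(table: np.ndarray, expected: np.ndarray) -> float:
    return float(((table - expected) ** 2 / expected).sum())


def _enumerate_exact_p(table: np.ndarray, max_tables: int = 2_000_000) -> Optional[float]:
    """Exact conditional p by full enumeration of margin-fixed tables.

    The null probability of a table with fixed margins is the multivariate
    hypergeometric mass; the p-value sums the mass of tables whose Pearson
    statistic >= the observed one.  Returns None if the (upper-bounded)
    enumeration size exceeds ``max_tables``.
    """
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    # size bound: compositions of each free row over the columns (the last
    # row is forced by the column margins)
    bound = 1.0
    c = len(cols)
    for r in rows[:-1]:
        bound *= math.comb(int(r) + c - 1, c - 1)
        if bound > max_tables:
            return None
    expected = np.outer(rows, cols) / n
    obs_stat = _pearson_chi2(table, expected)
    log_const = (sum(math.lgamma(r + 1) for r in rows)
                 + sum(math.lgamma(x + 1) for x in cols)
                 - math.lgamma(n + 1))
    p_total = 0.0

    def recurse(row_idx: int, remaining_cols: np.ndarray, cells: list[int]):
        nonlocal p_total
        if row_idx == len(rows) - 1:
            final = np.append(np.array(cells), remaining_cols).reshape(len(rows), c)
            stat = _pearson_chi2(final, expected)
            if stat >= obs_stat - 1e-9:
                log_p = log_const - sum(math.lgamma(x + 1) for x in final.ravel())
                p_total += math.exp(log_p)
            return
        target = int(rows[row_idx])

        def fill(col_idx: int, left: int, row_cells: list[int]):
            if col_idx == c - 1:
                if left <= remaining_cols[col_idx]:
                    recurse(row_idx + 1,
                            remaining_cols - np.array(row_cells + [left]),
                            cells + row_cells + [left])
                return
            for x in range(min(left, int(remaining_cols[col_idx])) + 1):
                fill(col_idx + 1, left - x, row_cells + [x])

        fill(0, target, [])

    recurse(0, cols.astype(int).copy(), [])
    return min(1.0, p_total)


def exact_chi_square_p(table: Sequence[Sequence[int]],
                       n_resamples: int = 9999,
                       rng: Optional[np.random.Generator] = None) -> float:
    """Exact conditional p-value for the Pearson chi-square statistic.

    Full enumeration when feasible; otherwise Monte Carlo over margin-fixed
    tables (add-one estimator), using ``rng`` for reproducibility.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    p = _enumerate_exact_p(t)
    if p is not None:
        return p
    rng = rng or np.random.default_rng(0)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    expected = np.outer(rows, cols) / t.sum()
    obs = _pearson_chi2(t, expected)
    sampler = stats.random_table(rows, cols)
    sims = sampler.rvs(n_resamples, random_state=rng)
    stats_sim = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    return float((1 + np.sum(stats_sim >= obs - 1e-9)) / (1 + n_resamples))


def compare_categorical(table: Sequence[Sequence[int]], exact: bool = False,
                        variable: str = "",
                        rng: Optional[np.random.Generator] = None) -> GroupComparison:
    """Pearson chi-square test of independence on an r x c count table.

    With ``exact=True`` the p-value is the exact conditional tail
    probability (Pearson statistic as ordering criterion); otherwise the
    asymptotic chi-square p (no continuity correction).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(t, correction=False)
    if exact:
        p = exact_chi_square_p(t, rng=rng)
        method = "chi_square_exact"
    else:
        p = float(res.pvalue)
        method = "chi_square"
    return GroupComparison(variable=variable, method=method,
                           statistic=float(res.statistic), p_value=float(p),
                           group_summaries={"table": t.tolist()},
                           n=int(t.sum()))


def kruskal_wallis(values: Sequence[float], groups: Sequence,
                   variable: str = "") -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected) of a numeric variable across
    >= 2 group levels."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    levels = [lv for lv in np.unique(g)]
    if len(levels) < 2:
        raise ValueError("need >= 2 group levels")
    samples = [v[g == lv] for lv in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group level")
    if np.all(v == v[0]):
        # all observations tied: H = 0, p = 1 (scipy errors on all-tied data)
        return GroupComparison(variable=variable, method="kruskal_wallis",
                               statistic=0.0, p_value=1.0, n=int(len(v)))
    res = stats.kruskal(*samples)
    return GroupComparison(
        variable=variable, method="kruskal_wallis",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        group_summaries={str(lv): {"n": int(len(s)), "median": float(np.median(s))}
                         for lv, s in zip(levels, samples)},
        n=int(len(v)),
    )
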