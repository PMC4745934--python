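"""Rounding-aware integer confusion-matrix reconstruction.

Published diagnostic tables print sensitivity, specificity, predictive
values and accuracy as rounded percentages but rarely the underlying 2x2
counts.  Because each percentage is a ratio of small integers, exhaustive
enumeration over all integer tables up to a cohort-size cap recovers every
table consistent with the printed values — often a unique minimal one.
Reconstructed tables then serve as exact fixtures: feeding one back through
:func:`pcps.diagnostics.diagnostic_report` must reproduce all printed
intervals, which simultaneously cross-checks the reconstruction and the
interval-method identification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._rounding import round_display
from .diagnostics import ConfusionMatrix, diagnostic_report

__all__ = ["RoundedMetrics", "ReconstructionResult", "reconstruct", "verify_against_cis"]


@dataclass(frozen=True)
class RoundedMetrics:
    """Printed (rounded) operating characteristics of a binary test.

    Percentages carry one decimal; ``n_max`` caps each arm (diseased and
    non-diseased) of the search.  ``rounding`` selects the tie-breaking rule
    assumed for the published table ("half_up" or "half_even").
    """

    sen_pct: float
    spe_pct: float
    ppv_pct: Optional[float] = None
    npv_pct: Optional[float] = None
    accuracy_pct: Optional[float] = None
    n_max: int = 71
    rounding: str = "half_up"
    decimals: int = 1

    def __post_init__(self) -> None:
        for name in ("sen_pct", "spe_pct", "ppv_pct", "npv_pct", "accuracy_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100]")
        if self.n_max < 2:
            raise ValueError("n_max must be >= 2")


@dataclass(frozen=True)
class ReconstructionResult:
    """All consistent tables, sorted by total n (then lexicographically)."""

    candidates: tuple[ConfusionMatrix, ...]
    is_unique_minimal: bool

    @property
    def minimal(self) -> Optional[ConfusionMatrix]:
        return self.candidates[0] if self.candidates else None


def _matches(k: int, n: int, target_pct: float, decimals: int, mode: str) -> bool:
    return round_display(100.0 * k / n, decimals, mode) == round_display(
        target_pct, decimals, mode)


def reconstruct(metrics: RoundedMetrics) -> ReconstructionResult:
    """Enumerate every integer 2x2 table consistent with the printed metrics.

    Scans tp+fn <= n_max and tn+fp <= n_max, keeping tables whose
    display-rounded sensitivity/specificity (and any supplied PPV, NPV,
    accuracy) equal the printed values.  An empty candidate list means no
    table within the cap reproduces the inputs.
    """
    dec, mode = metrics.decimals, metrics.rounding
    pos_arms = [(tp, npos - tp)
                for npos in range(1, metrics.n_max + 1)
                for tp in range(npos + 1)
                if _matches(tp, npos, metrics.sen_pct, dec, mode)]
    neg_arms = [(tn, nneg - tn)
                for nneg in range(1, metrics.n_max + 1)
                for tn in range(nneg + 1)
                if _matches(tn, nneg, metrics.spe_pct, dec, mode)]
    candidates = []
    for tp, fn in pos_arms:
        for tn, fp in neg_arms:
            if metrics.ppv_pct is not None:
                if tp + fp == 0 or not _matches(tp, tp + fp, metrics.ppv_pct, dec, mode):
                    continue
            if metrics.npv_pct is not None:
                if tn + fn == 0 or not _matches(tn, tn + fn, metrics.npv_pct, dec, mode):
                    continue
            if metrics.accuracy_pct is not None:
                total = tp + fn + fp + tn
                if not _matches(tp + tn, total, metrics.accuracy_pct, dec, mode):
                    continue
            candidates.append(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
    candidates.sort(key=lambda c: (c.n, c.tp, c.fn, c.fp, c.tn))
    unique_min = (len(candidates) == 1
                  or (len(candidates) > 1 and candidates[0].n < candidates[1].n))
    return ReconstructionResult(candidates=tuple(candidates),
                                is_unique_minimal=unique_min)


def verify_against_cis(cm: ConfusionMatrix, printed: dict,
                       mode: str = "half_up") -> bool:
    """Check that a reconstructed table reproduces printed 95% intervals.

    ``printed`` maps any of ``ci_sen``, ``ci_spe``, ``ci_ppv``, ``ci_npv``
    (percentage scale, 1 decimal) and ``ci_lr_pos``, ``ci_lr_neg`` (ratio
    scale, 2 decimals) to (lower, upper) pairs as printed.  Returns True iff
    the display-rounded intervals of :func:`diagnostic_report` match every
    supplied pair — a simultaneous check of the reconstruction and the
    interval-method choices.
    """
    rd = diagnostic_report(cm).rounded_dict(mode)
    for key, bounds in printed.items():
        if key not in rd:
            raise KeyError(f"unknown interval name {key!r}")
        got = rd[key]
        if got is None:
            return False
        if tuple(got) != (float(bounds[0]), float(bounds[1])):
            return False
    return True
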