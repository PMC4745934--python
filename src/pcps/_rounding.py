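"""Display-rounding helpers.

Clinical tables conventionally print percentages to one decimal and ratios
(likelihood ratios, AUC) to two, rounding halves away from zero.  Matching a
published table therefore requires reproducing that convention exactly rather
than relying on Python's banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

_MODES = {"half_up": ROUND_HALF_UP, "half_even": ROUND_HALF_EVEN}


def round_display(x: float, decimals: int = 1, mode: str = "half_up") -> float:
    """Round ``x`` to ``decimals`` places under the given tie-breaking mode.

    ``mode`` is ``"half_up"`` (ties away from zero, the usual convention of
    clinical statistics software) or ``"half_even"`` (IEEE banker's rounding).
    """
    if mode not in _MODES:
        raise ValueError(f"unknown rounding mode {mode!r}")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=_MODES[mode]))


def round_pct(x: float, mode: str = "half_up") -> float:
    """Round a percentage to one decimal (table display convention)."""
    return round_display(x, 1, mode)


def round_ratio(x: float, mode: str = "half_up") -> float:
    """Round a ratio (LR, AUC) to two decimals (table display convention)."""
    return round_display(x, 2, mode)
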