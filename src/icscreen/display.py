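"""Percentage formatting with half-away-from-zero rounding.

Displayed percentages round half away from zero to a fixed number of
decimals; all classification logic elsewhere uses unrounded fractions.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

from .core import DataError

__all__ = ["round_half_away", "percent_value", "percent_display"]


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round to ``decimals`` places, halves going away from zero.

    Decimal-based, so 0.5-at-the-last-place cases are exact rather than
    subject to binary-float banker's rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_value(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half away from zero.

    Computed as an exact rational before quantizing, so e.g. 16/151 gives
    10.6 at one decimal.
    """
    if denominator == 0:
        raise DataError("percent of a zero denominator is undefined")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def percent_display(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Format ``numerator/denominator`` as a percentage string like ``"27.2%"``."""
    value = percent_value(numerator, denominator, decimals)
    return f"{value:.{decimals}f}%"
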