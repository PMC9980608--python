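"""Report-layer formatting helpers.

Internally every proportion is a fraction; conversion to display percentages
happens only here, with half-up rounding to a fixed number of decimals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(numerator: float, denominator: float | None = None, digits: int = 1) -> float:
    """Format a fraction (or a count pair) as a percentage.

    ``percent(0.158)`` and ``percent(342, 2171)`` both give ``15.8``.
    Rounding is half-up on the decimal representation, matching how
    percentages are conventionally printed.
    """
    if denominator is not None:
        if denominator == 0:
            raise ZeroDivisionError("percent() with zero denominator")
        value = 100.0 * numerator / denominator
    else:
        value = 100.0 * numerator
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
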