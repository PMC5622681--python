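"""Half-up display rounding.

All scoring arithmetic in this package is carried out unrounded; regulatory
tables print 1-decimal intermediates (grams, ratings, %DV) and 2-decimal PER
values, and threshold verdicts in those tables are taken on the printed
numbers. ``round_half_up`` reproduces that convention (Python's builtin
``round`` is banker's rounding and would turn 10.75 into 10.7, not 10.8).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties away from zero.

    Operates on the shortest decimal representation of the float, so values
    that print as exact decimals (e.g. 10.75) round the way they read.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
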