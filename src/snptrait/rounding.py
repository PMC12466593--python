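"""Half-away-from-zero rounding for report display.

All statistics are computed at full double precision; rounding happens only
when a report is rendered. Python's built-in ``round`` is banker's rounding,
which disagrees with how statistical tables are conventionally printed, so
display rounding goes through :func:`round_half_up`.
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
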