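"""Half-up decimal rounding used for every reported ratio and percentage.

Python's built-in ``round`` is banker's rounding; regulatory summary tables
round half away from zero, so 2.105 must print as 2.11, not 2.10.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero.

    The value is converted through ``repr`` so the decision is made on the
    shortest decimal representation of the float, not on its binary expansion.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
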