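"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round *x* to *ndigits* decimals, ties going away from zero.

    Survey tables conventionally print 0.5 -> 1 and 66.65 -> 66.7; Python's
    built-in banker's rounding would disagree on exact ties, so rounding goes
    through :mod:`decimal` on the shortest repr of the float.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
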