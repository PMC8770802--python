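"""Presentation helpers: exact-fraction rounding and JSON-safe encoding."""

from __future__ import annotations

import decimal
from fractions import Fraction

__all__ = ["round_half_up", "fraction_payload"]


def round_half_up(value: Fraction | float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Exact rationals are rounded exactly; floats are routed through
    :class:`decimal.Decimal` so 2.675 → 2.68, not 2.67.
    """
    with decimal.localcontext() as ctx:
        ctx.prec = 60
        if isinstance(value, Fraction):
            d = decimal.Decimal(value.numerator) / decimal.Decimal(value.denominator)
        else:
            d = decimal.Decimal(repr(float(value)))
        q = decimal.Decimal(1).scaleb(-ndigits)
        return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))


def fraction_payload(value: Fraction | float | None, ndigits: int) -> dict | None:
    """JSON block for one metric: exact fraction plus rounded display value."""
    if value is None:
        return None
    payload: dict = {"value": float(value), "display": round_half_up(value, ndigits)}
    if isinstance(value, Fraction):
        payload["fraction"] = {
            "num": value.numerator,
            "den": value.denominator,
        }
    return payload
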