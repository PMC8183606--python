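"""Rounding conventions used throughout the decision model.

Counts are rounded half-away-from-zero at every ``rate x count`` node and the
complementary branch is obtained by subtraction, so conservation identities
hold exactly. Money is carried as :class:`decimal.Decimal` quantized to cents.
Floats are routed through ``repr`` so that representation noise (e.g.
``115 * 0.58 == 66.69999999999999``) does not flip a rounding decision.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

_CENT = Decimal("0.01")
_ONE = Decimal(1)

Number = int | float | Fraction | Decimal


def _as_decimal(x: Number) -> Decimal:
    if isinstance(x, Decimal):
        return x
    if isinstance(x, int):
        return Decimal(x)
    if isinstance(x, Fraction):
        return Decimal(x.numerator) / Decimal(x.denominator)
    return Decimal(repr(x))


def round_half_up(x: Number) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(_as_decimal(x).quantize(_ONE, rounding=ROUND_HALF_UP))


def to_cents(x: Number) -> Decimal:
    """Quantize a monetary amount to cents, halves away from zero."""
    return _as_decimal(x).quantize(_CENT, rounding=ROUND_HALF_UP)
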