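"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Reported percent changes and bias-adjusted exposures use this convention
    (e.g. 76.625 -> 77), which differs from banker's rounding of ``round``.
    """
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def round_to_hundred(x: float) -> int:
    """Round to the nearest multiple of 100 (halves away from zero)."""
    return 100 * int(
        (Decimal(repr(float(x))) / 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
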