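"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), not banker's rounding.

    Printed survey tables round 90.05 -> 90.1; Python's built-in ``round``
    would give 90.0.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denominator: int, ndigits: int = 1) -> float | None:
    """Percentage rounded half-up; ``None`` when the denominator is zero."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * count / denominator, ndigits)
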