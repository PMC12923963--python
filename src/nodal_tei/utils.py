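"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of clinical tables.

    Python's builtin ``round`` uses banker's rounding (2.25 -> 2.2); the
    printed indices round half up (2.25 -> 2.3).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: int, n: int, ndigits: int = 1) -> float:
    """Proportion ``k/n`` on the percentage scale, rounded half-up."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * k / n, ndigits)
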