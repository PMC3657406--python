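"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, the convention of printed tables.

    Python's built-in ``round`` is banker's rounding; printed percentages in
    the pharmacology literature are half-up (34.845 -> 34.85 at 2 digits).
    Goes through the decimal string representation so binary float artifacts
    (e.g. 2.675 stored as 2.67499...) do not flip the tie direction.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
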