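"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at *ndigits* decimals (0.335 -> 0.34).

    Python's builtin round() is banker's rounding; printed tables in the
    pharmacology literature use half-up, so presentation goes through this.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
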