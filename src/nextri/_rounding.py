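"""Decimal round-half-up helpers for printed percentages.

Laboratory tables round 2.675 -> 2.68 (half away from zero), which differs
from Python's banker's rounding; all printed rates go through these helpers.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` half-up to ``ndigits`` decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rate_percent(count: int, total: int, ndigits: int = 2) -> float:
    """Exact-integer percentage ``count/total*100`` rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))
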