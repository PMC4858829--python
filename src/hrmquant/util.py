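"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` is banker's rounding; reported methylation
    percentages use the conventional half-away-from-zero rule instead
    (24.275 -> 24.3, 68.625 -> 68.6).
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)
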