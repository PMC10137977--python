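"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals.

    Python's built-in ``round`` is banker's rounding; clinical-style
    percentages (57.89, 31.58, ...) and two-decimal frequency ratios are
    conventionally rounded half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
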