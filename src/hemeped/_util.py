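"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Python's built-in ``round`` uses banker's rounding (36.5 -> 36); the
    tabulation conventions here require 36.5 -> 37, 13.25 -> 13.3 etc.
    """
    q = Decimal(1).scaleb(-ndigits)
    out = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return out if ndigits > 0 else float(int(out))
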