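"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as survey software prints tables.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the half-up convention on exact .5 ties (e.g. 15.975 -> 15.97).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
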