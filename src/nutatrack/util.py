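"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimal places.

    Display rounding for tables uses the spreadsheet convention (0.5 -> 1),
    not Python's banker's rounding. Internal computations always keep full
    precision; this is applied only when rendering.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def round_half_up_int(x: float) -> int:
    return int(round_half_up(x, 0))
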