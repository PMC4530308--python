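"""Small shared numerics helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (3.25 -> 3.3 at 1 digit).

    Python's builtin ``round`` uses banker's rounding (3.25 -> 3.2),
    which is not how the report-style figures here were rounded.  The
    value is first normalized to 12 significant digits so binary noise
    (3.8 / 0.8 = 4.749999999999999) does not flip a tie downward.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{x:.12g}").quantize(q, rounding=ROUND_HALF_UP))
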