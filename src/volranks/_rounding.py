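"""Display-rounding helpers.

Model coefficients and predictions are reported to four significant
figures; relative percent errors are reported to the nearest integer,
halves rounded away from zero. Full precision is kept internally —
these helpers are only applied at the reporting boundary.
"""

from __future__ import annotations

import math


def round_sig(x: float, sig: int = 4) -> float:
    """Round ``x`` to ``sig`` significant figures.

    Uses the decimal-digit rounding of the underlying binary float
    (ties resolved by the float's actual value, which is never exactly
    at a decimal half).
    """
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
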