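"""Report-boundary formatting helpers.

Internal values stay at full precision; rounding happens only when a
table is written.  Half-up rounding mirrors how such tables are usually
typeset (banker's rounding would flip some .x5 cells).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_mean_sd(mean: float, sd: float, ndigits: int = 4) -> str:
    """'0.1972 ± 0.1919'-style cell; 'n/a' when the mean is undefined."""
    if math.isnan(mean):
        return "n/a"
    return f"{round_half_up(mean, ndigits):.{ndigits}f} ± {round_half_up(sd, ndigits):.{ndigits}f}"
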