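"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

NUC_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_NUC = "ACGT"


def round_sig(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -(exponent - (ndigits - 1)))


def render_percent(proportion: float) -> str:
    """Render a proportion as a percentage string.

    Values below 0.01% are shown at one significant figure, everything else
    at two, matching how small between-genome divergences are conventionally
    reported (e.g. 28/704,883 -> "0.004%").
    """
    pct = proportion * 100.0
    sig = 1 if pct < 0.01 else 2
    return f"{round_sig(pct, sig):g}%"
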