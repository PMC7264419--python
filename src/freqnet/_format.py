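"""Number formatting shared by diagrams, stimuli and the CLI.

Probabilities are printed as percentages (default one decimal, trailing
zeros trimmed: "80%", "1.6%", "0.5%"); counts with thousands separators
("1,140"), matching the style of printed teaching material.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Union

Number = Union[int, float, Fraction]


def round_half_up(value: Fraction, decimals: int = 0) -> Fraction:
    scale = Fraction(10) ** decimals
    return Fraction(math.floor(value * scale + Fraction(1, 2)), 1) / scale


def format_percent(value: Number, decimals: int = 1) -> str:
    """'0.016' -> '1.6%'; trims trailing zeros after rounding half-up."""
    fr = value if isinstance(value, Fraction) else Fraction(str(value))
    pct = round_half_up(fr * 100, decimals)
    if pct.denominator == 1:
        return f"{int(pct)}%"
    text = f"{float(pct):.{decimals}f}".rstrip("0").rstrip(".")
    return f"{text}%"


def format_count(value: Number) -> str:
    """'10000' -> '10,000'; non-integral counts keep one decimal."""
    fr = value if isinstance(value, Fraction) else Fraction(str(value))
    if fr.denominator == 1:
        return f"{int(fr):,}"
    return f"{float(fr):,.1f}"
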