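"""Identifiers for the 16 probabilities of a two-binary-event situation.

A situation with two dichotomous events A and B carries 16 probabilities:
four marginals, four joints and eight conditionals, plus the total
(certain event) used as the reference for absolute frequencies.  Every
quantity has a canonical machine string ("P(A)", "P(notA)", "P(A&B)",
"P(A|notB)", "total") used in spec files and on the command line.
"""

from __future__ import annotations

import enum
import re
from typing import Optional, Tuple

__all__ = [
    "QuantityId",
    "parse_quantity",
    "LOWERCASE_SYMBOLS",
    "UPPERCASE_SYMBOLS",
]


class QuantityId(enum.Enum):
    """One of the 17 identifiable quantities (16 probabilities + total)."""

    TOTAL = "total"
    # marginals
    A = "P(A)"
    NOT_A = "P(notA)"
    B = "P(B)"
    NOT_B = "P(notB)"
    # joints (cells of the 2x2 situation)
    A_AND_B = "P(A&B)"
    A_AND_NOT_B = "P(A&notB)"
    NOT_A_AND_B = "P(notA&B)"
    NOT_A_AND_NOT_B = "P(notA&notB)"
    # conditionals
    A_GIVEN_B = "P(A|B)"
    NOT_A_GIVEN_B = "P(notA|B)"
    A_GIVEN_NOT_B = "P(A|notB)"
    NOT_A_GIVEN_NOT_B = "P(notA|notB)"
    B_GIVEN_A = "P(B|A)"
    NOT_B_GIVEN_A = "P(notB|A)"
    B_GIVEN_NOT_A = "P(B|notA)"
    NOT_B_GIVEN_NOT_A = "P(notB|notA)"

    def __str__(self) -> str:  # canonical serialization
        return self.value

    # ---- structural accessors -------------------------------------------

    @property
    def kind(self) -> str:
        """'total', 'marginal', 'joint' or 'conditional'."""
        if self is QuantityId.TOTAL:
            return "total"
        if "|" in self.value:
            return "conditional"
        if "&" in self.value:
            return "joint"
        return "marginal"

    @property
    def events(self) -> Tuple[str, ...]:
        """Atomic event tokens, e.g. P(A|notB) -> ('A', 'notB')."""
        if self is QuantityId.TOTAL:
            return ()
        inner = self.value[2:-1]
        return tuple(re.split(r"[&|]", inner))

    @property
    def conditioning_event(self) -> Optional[str]:
        """Token after the bar for conditionals, else None."""
        if self.kind != "conditional":
            return None
        return self.value[2:-1].split("|")[1]

    @property
    def target_event(self) -> Optional[str]:
        """Token before the bar for conditionals, else None."""
        if self.kind != "conditional":
            return None
        return self.value[2:-1].split("|")[0]


_BY_STRING = {q.value: q for q in QuantityId}

# accepted synonyms for atomic event tokens
_TOKEN_ALIASES = {
    "a": "A",
    "b": "B",
    "nota": "notA",
    "notb": "notB",
    "~a": "notA",
    "~b": "notB",
    "!a": "notA",
    "!b": "notB",
    "¬a": "notA",
    "¬b": "notB",
}


def _norm_token(tok: str) -> str:
    tok = tok.strip()
    key = tok.lower().replace(" ", "")
    if key not in _TOKEN_ALIASES:
        raise ValueError(f"unknown event token {tok!r}")
    return _TOKEN_ALIASES[key]


def parse_quantity(text: str) -> QuantityId:
    """Parse a canonical (or lightly aliased) quantity string.

    Accepts e.g. "P(A)", "p(not a | not b)", "P(notA&B)", "total",
    "P(A∩B)" and "P(¬A|B)".
    """
    s = text.strip()
    if s.lower() in ("total", "n"):
        return QuantityId.TOTAL
    m = re.fullmatch(r"[Pp]\((.+)\)", s)
    if not m:
        raise ValueError(f"cannot parse quantity string {text!r}")
    inner = m.group(1).replace("∩", "&")
    if "|" in inner:
        left, right = inner.split("|", 1)
        canon = f"P({_norm_token(left)}|{_norm_token(right)})"
    elif "&" in inner:
        left, right = inner.split("&", 1)
        canon = f"P({_norm_token(left)}&{_norm_token(right)})"
    else:
        canon = f"P({_norm_token(inner)})"
    if canon not in _BY_STRING:
        # normalise joint order: A-part first
        if "&" in canon:
            left, right = canon[2:-1].split("&")
            canon2 = f"P({right}&{left})"
            if canon2 in _BY_STRING:
                return _BY_STRING[canon2]
        raise ValueError(f"cannot parse quantity string {text!r}")
    return _BY_STRING[canon]


# ---------------------------------------------------------------------------
# Schematic letter notation.
#
# The error-strategy literature abbreviates the probabilities with lowercase
# letters and the absolute frequencies with the corresponding uppercase
# letters (A = the total sample, B = the count of the first event, F = the
# count of the A-and-B cell, ...).  The letters e, h, i and the uppercase
# E, H, I are not spelled out in the source tables and are completed here
# by the obvious pattern (complement columns of d, f, g / D, F, G).

LOWERCASE_SYMBOLS = {
    "b": QuantityId.A,
    "c": QuantityId.NOT_A,
    "d": QuantityId.B,
    "e": QuantityId.NOT_B,
    "f": QuantityId.A_AND_B,
    "g": QuantityId.NOT_A_AND_B,
    "h": QuantityId.A_AND_NOT_B,
    "i": QuantityId.NOT_A_AND_NOT_B,
    "j": QuantityId.B_GIVEN_A,
    "k": QuantityId.A_GIVEN_B,
    "l": QuantityId.NOT_A_GIVEN_B,
    "m": QuantityId.B_GIVEN_NOT_A,
    "n": QuantityId.NOT_B_GIVEN_NOT_A,
    "p": QuantityId.A_GIVEN_NOT_B,
    "q": QuantityId.NOT_B_GIVEN_A,
}

# uppercase letter -> the quantity whose absolute count it denotes
UPPERCASE_SYMBOLS = {
    "A": QuantityId.TOTAL,
    "B": QuantityId.A,
    "C": QuantityId.NOT_A,
    "D": QuantityId.B,
    "E": QuantityId.NOT_B,
    "F": QuantityId.A_AND_B,
    "G": QuantityId.NOT_A_AND_B,
    "H": QuantityId.A_AND_NOT_B,
    "I": QuantityId.NOT_A_AND_NOT_B,
}
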