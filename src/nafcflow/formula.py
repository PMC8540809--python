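"""Molecular-formula chemistry for naphthenic acid fraction compounds (NAFCs).

NAFCs are the acid-extractable organics of oil sands process-affected water
(OSPW) with the general formula :math:`C_cH_hN_nO_oS_s`.  This module parses
neutral Hill-style formula strings over C/H/N/O/S, computes double-bond
equivalents (DBE, rings plus pi-bonds), and assigns each composition to one of
the eight heteroatom classes used throughout petroleomics: CH, N, NS, NO, O,
NOS, S and SO — the :math:`2^3` presence/absence patterns of N, O and S.

"Classic" naphthenic acids are the :math:`C_cH_hO_2` subset (exactly two
oxygens, no nitrogen or sulfur) and are the principal OSPW toxicants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "CLASS_LABELS",
    "ElementCounts",
    "FormulaError",
    "classify",
    "dbe",
    "has_integral_dbe",
    "in_reported_carbon_range",
    "is_classic_na",
    "parse_formula",
    "species_label",
]

#: The eight heteroatom classes, in the conventional display order.
CLASS_LABELS = ("CH", "N", "NS", "NO", "O", "NOS", "S", "SO")

#: Carbon range typically reported for NAFCs.
REPORTED_CARBON_RANGE = (7, 26)

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_ALLOWED = {"C": "c", "H": "h", "N": "n", "O": "o", "S": "s"}


class FormulaError(ValueError):
    """Raised for formula strings outside the C/H/N/O/S NAFC dialect."""


@dataclass(frozen=True, order=True)
class ElementCounts:
    """Integer elemental composition (c, h, n, o, s) of one neutral formula."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise FormulaError(f"element count {name}={v!r} must be a non-negative integer")

    @property
    def formula(self) -> str:
        """Canonical Hill string: C, H, then N, O, S; subscript 1 omitted."""
        parts = []
        for sym, v in (("C", self.c), ("H", self.h), ("N", self.n), ("O", self.o), ("S", self.s)):
            if v == 1:
                parts.append(sym)
            elif v > 1:
                parts.append(f"{sym}{v}")
        return "".join(parts)


def parse_formula(text: str, strict: bool = False) -> ElementCounts:
    """Parse a neutral Hill-style formula over C, H, N, O, S.

    Parsing is independent of the order of element tokens; repeated tokens
    accumulate.  Elements outside the NAFC dialect raise
    :class:`FormulaError` rather than being dropped, so downstream class
    assignment stays sound.  With ``strict=True``, compositions without at
    least one carbon and one hydrogen are rejected as non-NAFC candidates.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"not a formula string: {text!r}")
    counts = {"c": 0, "h": 0, "n": 0, "o": 0, "s": 0}
    pos = 0
    t = text.strip()
    for m in _TOKEN_RE.finditer(t):
        if m.start() != pos:
            raise FormulaError(f"cannot parse {text!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in _ALLOWED:
            raise FormulaError(f"element {sym!r} in {text!r} is outside the C/H/N/O/S NAFC dialect")
        counts[_ALLOWED[sym]] += int(num) if num else 1
        pos = m.end()
    if pos != len(t):
        raise FormulaError(f"cannot parse {text!r} at position {pos}")
    ec = ElementCounts(**counts)
    if strict and (ec.c < 1 or ec.h < 1):
        raise FormulaError(f"{text!r}: an NAFC candidate needs c >= 1 and h >= 1")
    return ec


# small cache: MS tables repeat formulas heavily
@lru_cache(maxsize=65536)
def _parse_cached(text: str) -> ElementCounts:
    return parse_formula(text)


def dbe(ec: ElementCounts) -> float:
    """Double-bond equivalents: c + (n - h)/2 + 1.

    Divalent O and S contribute nothing, so only c, h and n enter.  The value
    is half-integral when n + h is odd (radical/ion compositions); it is
    returned unrounded — see :func:`has_integral_dbe`.
    """
    return ec.c + (ec.n - ec.h) / 2.0 + 1.0


def has_integral_dbe(ec: ElementCounts) -> bool:
    """True when the DBE is a whole number, i.e. n + h is even."""
    return (ec.n + ec.h) % 2 == 0


def classify(ec: ElementCounts) -> str:
    """Assign one of the eight heteroatom classes from N/O/S presence.

    The class depends only on which of n, o, s are positive; CH when all
    three are zero.  Total over all compositions: every input maps to exactly
    one of the eight labels.
    """
    key = (ec.n > 0, ec.o > 0, ec.s > 0)
    return {
        (False, False, False): "CH",
        (True, False, False): "N",
        (True, False, True): "NS",
        (True, True, False): "NO",
        (False, True, False): "O",
        (True, True, True): "NOS",
        (False, False, True): "S",
        (False, True, True): "SO",
    }[key]


def species_label(ec: ElementCounts) -> str:
    """Canonical fine label from heteroatom counts, e.g. ``N2O2`` or ``SO3``.

    Zero-count elements are omitted, as is the subscript 1 ("NO", not
    "N1O1"); element order is N, O, S.  Pure hydrocarbons are labelled "CH".
    """
    if ec.n == 0 and ec.o == 0 and ec.s == 0:
        return "CH"
    parts = []
    for sym, v in (("N", ec.n), ("O", ec.o), ("S", ec.s)):
        if v == 1:
            parts.append(sym)
        elif v > 1:
            parts.append(f"{sym}{v}")
    return "".join(parts)


def is_classic_na(ec: ElementCounts) -> bool:
    """True for classic naphthenic acids CcHhO2 (o == 2, no N or S)."""
    return ec.o == 2 and ec.n == 0 and ec.s == 0


def in_reported_carbon_range(ec: ElementCounts, lo: int = REPORTED_CARBON_RANGE[0],
                             hi: int = REPORTED_CARBON_RANGE[1]) -> bool:
    """Flag whether the carbon count lies in the typically reported NAFC range.

    This is a flag, not a filter: surveys also report classic NAs down to
    five and up to twenty-five carbons, so callers decide what to drop.
    """
    return lo <= ec.c <= hi
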