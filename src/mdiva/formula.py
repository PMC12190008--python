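"""Molecular formulas with exact monoisotopic masses.

Formulas are immutable element-count maps over the elements relevant to
dissolved organic matter chemistry (C, H, N, O, P, S, Cl).  Counts may be
negative, which is how reaction mass differences (product minus substrate)
are represented; a formula describing an actual molecule must be
non-negative, checked with :meth:`Formula.is_nonnegative`.
"""

from __future__ import annotations

import re
from typing import Iterator, Mapping

# Monoisotopic masses of the lightest stable isotope, Da, fixed to six
# decimals for reproducibility.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Cl": 34.968853,
}

# Hill-ish display order: carbon, hydrogen, then the rest alphabetically.
_ELEMENT_ORDER = ("C", "H", "Cl", "N", "O", "P", "S")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


class Formula:
    """An element-count vector with an exact monoisotopic mass.

    Parameters
    ----------
    source:
        Either a formula string such as ``"C6H12O6"`` (counts may be
        negative, e.g. ``"H-2O1"`` for a dehydrogenation-plus-oxygenation
        delta) or a mapping of element symbol to integer count.
    """

    __slots__ = ("_counts",)

    def __init__(self, source: str | Mapping[str, int] = "") -> None:
        if isinstance(source, str):
            counts = self._parse(source)
        else:
            counts = {el: int(n) for el, n in source.items()}
        for el in counts:
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element {el!r}")
        self._counts: dict[str, int] = {el: n for el, n in counts.items() if n != 0}

    @staticmethod
    def _parse(text: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        pos = 0
        for match in _TOKEN_RE.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at offset {pos}")
            el, num = match.groups()
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = match.end()
            if pos == len(text):
                break
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at offset {pos}")
        return counts

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    @property
    def monoisotopic_mass(self) -> float:
        """Mass in Da; for a signed delta formula this is the mass delta."""
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in self._counts.items())

    def is_nonnegative(self) -> bool:
        return all(n >= 0 for n in self._counts.values())

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for el, n in other._counts.items():
            merged[el] = merged.get(el, 0) - n
        return Formula(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __str__(self) -> str:
        parts = []
        for el in _ELEMENT_ORDER:
            n = self._counts.get(el, 0)
            if n == 0:
                continue
            if n == 1:
                parts.append(el)
            else:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"Formula({str(self) or ''!r})"
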