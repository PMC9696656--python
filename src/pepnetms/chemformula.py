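"""Molecular formula arithmetic and exact monoisotopic masses.

Everything downstream (peptide compositions, fragment ions, ppm-level
annotation) reduces to element bookkeeping on small CHNOS formulas plus a
handful of pinned physical constants, so this module is deliberately
self-contained and exact.

Monoisotopic atomic masses are pinned to CODATA/AME values.  Cation m/z is
computed by subtracting one electron mass from the composition mass rather
than by adding a rounded "proton shortcut" to the neutral species; at the
sub-ppm level the two differ enough to matter for high-resolution QTOF data.
"""

from __future__ import annotations

import re
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "FormulaError",
    "MolecularFormula",
    "parse_formula",
    "formula_combine",
    "monoisotopic_mz",
    "dbe",
    "ppm_error",
]

#: Pinned monoisotopic atomic masses in Da.  Extensible: registering a new
#: symbol here makes it parseable; anything absent is rejected rather than
#: silently mis-massed.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207117,
}

ELECTRON_MASS: float = 0.00054857991
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


def _hill_order(symbol: str) -> tuple[int, str]:
    # Hill convention: C first, H second, remaining symbols alphabetical.
    return {"C": (0, ""), "H": (1, "")}.get(symbol, (2, symbol))


class MolecularFormula:
    """An immutable element-count map with an integer charge.

    Counts are non-negative; the empty formula has mass 0 and charge 0.
    Instances are hashable and support ``+``/``-`` (element-wise, charge
    included) and ``*`` by a non-negative integer.
    """

    __slots__ = ("_items", "charge")

    def __init__(self, counts: Mapping[str, int] | None = None, charge: int = 0):
        items = []
        for symbol, count in (counts or {}).items():
            if symbol not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {symbol!r}")
            if count < 0:
                raise FormulaError(f"negative count for element {symbol!r}")
            if count:
                items.append((symbol, int(count)))
        items.sort(key=lambda kv: _hill_order(kv[0]))
        object.__setattr__(self, "_items", tuple(items))
        object.__setattr__(self, "charge", int(charge))

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("MolecularFormula is immutable")

    # -- mapping-ish access -------------------------------------------------
    @property
    def counts(self) -> dict[str, int]:
        return dict(self._items)

    def __getitem__(self, symbol: str) -> int:
        for el, n in self._items:
            if el == symbol:
                return n
        return 0

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._items)

    def __bool__(self) -> bool:
        return bool(self._items)

    @property
    def is_empty(self) -> bool:
        return not self._items

    # -- identity -----------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self._items == other._items and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((self._items, self.charge))

    def __repr__(self) -> str:
        return f"MolecularFormula({self.format()!r})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return formula_combine(self, other, +1)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        return formula_combine(self, other, -1)

    def __mul__(self, n: int) -> "MolecularFormula":
        if n < 0:
            raise FormulaError("cannot multiply a formula by a negative integer")
        return MolecularFormula({el: c * n for el, c in self._items}, self.charge * n)

    __rmul__ = __mul__

    def with_charge(self, charge: int) -> "MolecularFormula":
        return MolecularFormula(self.counts, charge)

    # -- formatting ---------------------------------------------------------
    def format(self, include_charge: bool = True) -> str:
        body = "".join(
            el if n == 1 else f"{el}{n}" for el, n in self._items
        )
        if not include_charge or self.charge == 0:
            return body
        sign = "+" if self.charge > 0 else "-"
        mag = abs(self.charge)
        return body + (sign if mag == 1 else f"{mag}{sign}")

    def __str__(self) -> str:
        return self.format()

    @property
    def mass(self) -> float:
        """Monoisotopic mass of the composition, charge-corrected.

        For a charged formula this is the mass of the ion (composition mass
        minus ``charge`` electron masses); the division by charge to obtain
        m/z is a no-op for the singly charged species supported here.
        """
        m = sum(MONOISOTOPIC_MASS[el] * n for el, n in self._items)
        return m - self.charge * ELECTRON_MASS


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse ``"C46H65N8O8"``-style strings; a single trailing ``+``/``-``
    sets charge ±1.  Isotope notation is not supported."""
    charge = 0
    body = text.strip()
    if body.endswith("+"):
        charge, body = 1, body[:-1]
    elif body.endswith("-"):
        charge, body = -1, body[:-1]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        match = _TOKEN.match(body, pos)
        if not match or not match.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unknown element symbol {symbol!r} in formula {text!r}"
            )
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return MolecularFormula(counts, charge)


def formula_combine(
    a: MolecularFormula, b: MolecularFormula, sign: int = +1
) -> MolecularFormula:
    """Element-wise sum (``sign=+1``) or difference (``sign=-1``); charge
    adds/subtracts.  A difference driving any count negative is rejected
    naming the offending element."""
    if sign not in (+1, -1):
        raise FormulaError("sign must be +1 or -1")
    counts = a.counts
    for el, n in b:
        new = counts.get(el, 0) + sign * n
        if new < 0:
            raise FormulaError(
                f"subtraction would give a negative count for element {el!r}"
            )
        counts[el] = new
    return MolecularFormula(counts, a.charge + sign * b.charge)


def monoisotopic_mz(f: MolecularFormula) -> float:
    """Monoisotopic m/z (|charge| = 1) or neutral mass (charge 0) in Da."""
    if f.is_empty:
        raise FormulaError("cannot compute a mass for the empty formula")
    if abs(f.charge) > 1:
        raise FormulaError("multiply charged species are out of scope")
    return f.mass


def dbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents of a neutral CHNOS formula:
    ``C - H/2 + N/2 + 1`` (O and S contribute zero)."""
    if f.charge != 0:
        raise FormulaError("DBE is defined on neutral formulas only")
    return f["C"] - f["H"] / 2 + f["N"] / 2 + 1


def ppm_error(calculated: float, observed: float) -> float:
    """Signed relative mass deviation, ``(calc - obs) / calc * 1e6``.

    The sign convention matches how product-ion tables for this peptide
    family report their error column (calculated minus observed over
    calculated).
    """
    if calculated <= 0 or observed <= 0:
        raise ValueError("masses must be positive")
    return (calculated - observed) / calculated * 1e6
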