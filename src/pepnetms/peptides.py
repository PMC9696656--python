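"""Linear peptides with the terminal chemistries of the subarmigeride family.

The model covers the 20 standard residues plus Xle (Leu/Ile, indistinguishable
by mass), an N-terminal state of free amine, formyl (+CO, the formamide seen
in subarmigeride A) or carboxyl (+CO2, the carbamic-acid reading of the
"-COOH" terminus printed for two of the family's putative analogues), and a
C-terminal state of free acid or primary amide (net -O +NH relative to the
acid).

Sequence notation: the family is written in the literature in both
orientations — "CHO-Leu-Pro-...-Leu-NH2" (N-to-C) and the equivalent
"NH2-Leu-...-Leu-CHO" (amide end first).  The parser accepts both and
canonicalizes to N-terminus-first storage; formyl/carboxyl always end up on
the N-terminal backbone nitrogen, as fixed by the family's NMR evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache

from .chemformula import MolecularFormula, monoisotopic_mz, parse_formula

__all__ = [
    "RESIDUE_FORMULAS",
    "NTerm",
    "CTerm",
    "TerminalMods",
    "LinearPeptide",
    "PeptideError",
    "residue_formula",
    "residue_mass",
    "parse_sequence_notation",
    "neutral_formula",
    "precursor_mz",
]


class PeptideError(ValueError):
    """Raised for unknown residues or inconsistent terminal states."""


#: Chain-residue compositions (amino acid minus water).  Leu, Ile and the
#: mass-ambiguous Xle share one composition.
RESIDUE_FORMULAS: dict[str, str] = {
    "Gly": "C2H3NO",
    "Ala": "C3H5NO",
    "Ser": "C3H5NO2",
    "Pro": "C5H7NO",
    "Val": "C5H9NO",
    "Thr": "C4H7NO2",
    "Cys": "C3H5NOS",
    "Leu": "C6H11NO",
    "Ile": "C6H11NO",
    "Xle": "C6H11NO",
    "Asn": "C4H6N2O2",
    "Asp": "C4H5NO3",
    "Gln": "C5H8N2O2",
    "Lys": "C6H12N2O",
    "Glu": "C5H7NO3",
    "Met": "C5H9NOS",
    "His": "C6H7N3O",
    "Phe": "C9H9NO",
    "Arg": "C6H12N4O",
    "Tyr": "C9H9NO2",
    "Trp": "C11H10N2O",
}

#: Residues that are isobaric with Xle and collapse to it under strict
#: mass-only comparison.
_XLE_ALIASES = {"Leu", "Ile", "Xle"}


@lru_cache(maxsize=None)
def residue_formula(code: str) -> MolecularFormula:
    try:
        return parse_formula(RESIDUE_FORMULAS[code])
    except KeyError:
        raise PeptideError(f"unknown residue code {code!r}") from None


@lru_cache(maxsize=None)
def residue_mass(code: str) -> float:
    return residue_formula(code).mass


class NTerm(str, Enum):
    FREE_AMINE = "free_amine"
    FORMYL = "formyl"          # +CO on the backbone nitrogen
    CARBOXYL = "carboxyl"      # +CO2 (carbamic acid)


class CTerm(str, Enum):
    FREE_ACID = "free_acid"
    AMIDE = "amide"            # -O +NH relative to the free acid


@dataclass(frozen=True)
class TerminalMods:
    n_term: NTerm = NTerm.FREE_AMINE
    c_term: CTerm = CTerm.FREE_ACID


@dataclass(frozen=True)
class LinearPeptide:
    """An ordered residue list (N-terminus first) with terminal states."""

    residues: tuple[str, ...]
    mods: TerminalMods = field(default_factory=TerminalMods)
    name: str = ""

    def __post_init__(self):
        if len(self.residues) < 1:
            raise PeptideError("a peptide needs at least one residue")
        for code in self.residues:
            residue_formula(code)  # raises on unknown codes
        object.__setattr__(self, "residues", tuple(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_term(self) -> NTerm:
        return self.mods.n_term

    @property
    def c_term(self) -> CTerm:
        return self.mods.c_term

    def collapse_xle(self) -> "LinearPeptide":
        """Return the peptide with Leu/Ile collapsed to Xle (strict
        mass-comparison mode)."""
        collapsed = tuple(
            "Xle" if r in _XLE_ALIASES else r for r in self.residues
        )
        return replace(self, residues=collapsed)

    def notation(self) -> str:
        """N-to-C notation string, e.g. ``CHO-Leu-Pro-...-Leu-NH2``."""
        prefix = {NTerm.FREE_AMINE: "H", NTerm.FORMYL: "CHO", NTerm.CARBOXYL: "HOOC"}
        suffix = {CTerm.FREE_ACID: "OH", CTerm.AMIDE: "NH2"}
        parts = [prefix[self.n_term], *self.residues, suffix[self.c_term]]
        return "-".join(parts)


_N_TOKENS = {"CHO": NTerm.FORMYL, "HOOC": NTerm.CARBOXYL, "COOH": NTerm.CARBOXYL}


def _residue_token(token: str) -> str:
    t = token.strip()
    if "/" in t:  # "Leu/Ile" and friends are mass-ambiguous
        parts = {p.strip().capitalize() for p in t.split("/")}
        if parts <= _XLE_ALIASES:
            return "Xle"
        raise PeptideError(f"ambiguous residue token {token!r}")
    code = t.capitalize()
    if code not in RESIDUE_FORMULAS:
        raise PeptideError(f"unknown residue code {token!r}")
    return code


def parse_sequence_notation(
    text: str, *, family_convention: bool = False
) -> LinearPeptide:
    """Parse hyphen-separated sequence notation into a :class:`LinearPeptide`.

    Recognized terminal tokens: leading ``CHO-``/``HOOC-`` (N-terminal formyl
    or carboxyl, string read N-to-C), leading ``H-``/``NH2-``, trailing
    ``-NH2``/``-OH`` and trailing ``-CHO``/``-COOH``.  A *trailing* formyl or
    carboxyl token marks the string as written amide-end first (the family's
    alternative orientation): the residue order is reversed so that the
    modified nitrogen is stored at the N-terminus, and a leading ``NH2-``
    then denotes the C-terminal amide.

    With ``family_convention=True`` a string with a leading ``NH2-`` and no
    trailing marker is also read amide-end first with an implied C-amide (the
    convention of the analogue table rows that list no terminal group).
    Unmarked termini default to free amine / free acid.
    """
    raw = [t for t in text.replace(" ", "-").split("-") if t]
    if not raw:
        raise PeptideError("empty sequence notation")

    lead = raw[0].upper() if raw[0].upper() in ("CHO", "HOOC", "COOH", "NH2", "H") else None
    trail = (
        raw[-1].upper()
        if len(raw) > 1 and raw[-1].upper() in ("CHO", "COOH", "HOOC", "NH2", "OH")
        else None
    )
    core = raw[1 if lead else 0 : len(raw) - (1 if trail else 0)]
    if not core:
        raise PeptideError(f"no residues in notation {text!r}")
    residues = tuple(_residue_token(t) for t in core)

    if lead in _N_TOKENS:
        if trail in ("CHO", "COOH", "HOOC"):
            raise PeptideError("both termini carry a formyl/carboxyl group")
        n_term = _N_TOKENS[lead]
        c_term = CTerm.AMIDE if trail == "NH2" else CTerm.FREE_ACID
    elif trail in ("CHO", "COOH", "HOOC"):
        # amide-end-first orientation: reverse to N-to-C storage
        residues = residues[::-1]
        n_term = _N_TOKENS[trail]
        c_term = CTerm.AMIDE if lead == "NH2" else CTerm.FREE_ACID
    elif family_convention and trail is None and lead in (None, "NH2"):
        # amide-end-first listing with no orienting trailing token: a
        # leading NH2 is the C-terminal amide, a bare lead a free acid
        residues = residues[::-1]
        n_term = NTerm.FREE_AMINE
        c_term = CTerm.AMIDE if lead == "NH2" else CTerm.FREE_ACID
    else:
        n_term = NTerm.FREE_AMINE
        c_term = CTerm.AMIDE if trail == "NH2" else CTerm.FREE_ACID

    return LinearPeptide(residues, TerminalMods(n_term, c_term), name=text)


_H2O = parse_formula("H2O")
_CO = parse_formula("CO")
_CO2 = parse_formula("CO2")
_NH = parse_formula("NH")
_O = parse_formula("O")
_H = parse_formula("H")


def neutral_formula(p: LinearPeptide) -> MolecularFormula:
    """Neutral composition: residue sum + H2O backbone closure, then the
    terminal states (formyl +CO, carboxyl +CO2; amide -O +NH)."""
    f = _H2O
    for code in p.residues:
        f = f + residue_formula(code)
    if p.n_term is NTerm.FORMYL:
        f = f + _CO
    elif p.n_term is NTerm.CARBOXYL:
        f = f + _CO2
    if p.c_term is CTerm.AMIDE:
        f = f + _NH - _O
    return f


def precursor_mz(p: LinearPeptide, charge: int = 1) -> float:
    """[M+H]+ m/z of the peptide.  Only singly protonated species are
    supported."""
    if charge != 1:
        raise PeptideError("only charge +1 precursors are supported")
    cation = (neutral_formula(p) + _H).with_charge(+1)
    return monoisotopic_mz(cation)


def precursor_formula(p: LinearPeptide) -> MolecularFormula:
    """[M+H]+ cation composition."""
    return (neutral_formula(p) + _H).with_charge(+1)
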