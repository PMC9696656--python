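"""Theoretical singly charged fragment ions of a linear peptide.

Ion chemistry implemented (all as even-electron, singly protonated cations):

* precursor [M+H]+
* b ions (N-terminal, spans 1..i; an N-formyl or N-carboxyl group travels
  with the b/a series)
* a ions (b - CO)
* y ions (C-terminal, spans i..N; carry the C-terminal amide or acid)
* internal b-type ions (two backbone cleavages; acylium/oxazolone-type,
  spans touch neither terminus and have, by default, at least two residues)
* internal a-type ions (internal b - CO)
* immonium ions (single residue, residue - CO + H)
* neutral-loss satellites: -NH3 and -CO (each at most once, combinable) on
  b, y and internal b-type ions.

This minimal set is exactly what is needed to explain every product ion
reported for the subarmigeride family at few-ppm accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemformula import FormulaError, MolecularFormula, parse_formula
from .peptides import CTerm, LinearPeptide, NTerm, residue_formula

__all__ = [
    "IonSpecies",
    "FragmentationConfig",
    "FragmentationError",
    "ion_formula",
    "theoretical_ions",
    "ion_table_tsv",
]


class FragmentationError(ValueError):
    """Raised for invalid kind/span/loss combinations."""


_H = parse_formula("H")
_CO = parse_formula("CO")
_CO2 = parse_formula("CO2")
_NH = parse_formula("NH")
_NH2 = parse_formula("NH2")
_NH3 = parse_formula("NH3")
_OH = parse_formula("OH")
_H2O = parse_formula("H2O")

_LOSS_FORMULAS = {"NH3": _NH3, "CO": _CO, "H2O": _H2O}


@dataclass(frozen=True)
class IonSpecies:
    """One theoretical fragment: kind, 1-based inclusive residue span
    (N-terminal numbering), neutral losses, cation formula and m/z."""

    kind: str
    span: tuple[int, int]
    losses: frozenset[str]
    formula: MolecularFormula
    mz: float
    label: str

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class FragmentationConfig:
    kinds: tuple[str, ...] = (
        "precursor", "b", "a", "y", "internal_b", "internal_a", "immonium",
    )
    max_nh3_losses: int = 1
    max_co_losses: int = 1
    allow_combined_losses: bool = True
    min_internal_length: int = 2
    include_h2o_loss: bool = False

    def loss_sets(self) -> list[frozenset[str]]:
        singles = []
        if self.max_nh3_losses > 0:
            singles.append("NH3")
        if self.max_co_losses > 0:
            singles.append("CO")
        if self.include_h2o_loss:
            singles.append("H2O")
        sets = [frozenset()] + [frozenset({s}) for s in singles]
        if self.allow_combined_losses:
            for i, s1 in enumerate(singles):
                for s2 in singles[i + 1 :]:
                    sets.append(frozenset({s1, s2}))
        return sets


def _segment(p: LinearPeptide, span: tuple[int, int]) -> MolecularFormula:
    i, j = span
    if not (1 <= i <= j <= len(p)):
        raise FragmentationError(f"span {span} invalid for length {len(p)}")
    f = MolecularFormula()
    for code in p.residues[i - 1 : j]:
        f = f + residue_formula(code)
    return f


def _n_terminal_cap(p: LinearPeptide) -> MolecularFormula:
    if p.n_term is NTerm.FORMYL:
        return _H + _CO
    if p.n_term is NTerm.CARBOXYL:
        return _H + _CO2
    return _H


def ion_formula(
    p: LinearPeptide,
    kind: str,
    span: tuple[int, int],
    losses: frozenset[str] | tuple[str, ...] = (),
) -> MolecularFormula:
    """Cation composition of one fragment.  Raises
    :class:`FragmentationError` for spans invalid for the kind or losses the
    kind cannot carry (e.g. a further CO loss from an a-type ion)."""
    n = len(p)
    losses = frozenset(losses)
    if kind in ("a", "internal_a") and "CO" in losses:
        raise FragmentationError(f"CO loss not permitted on {kind} ions")
    if kind in ("precursor", "immonium") and losses:
        raise FragmentationError(f"losses not supported on {kind} ions")

    if kind == "precursor":
        from .peptides import neutral_formula

        f = neutral_formula(p) + _H
    elif kind in ("b", "a"):
        if span[0] != 1 or span[1] >= n:
            raise FragmentationError(f"b/a span must be 1..i with i < {n}")
        f = _segment(p, span) + _n_terminal_cap(p)
        if kind == "a":
            f = f - _CO
    elif kind == "y":
        if span[1] != n or span[0] <= 1:
            raise FragmentationError(f"y span must be i..{n} with i > 1")
        cterm = _NH2 if p.c_term is CTerm.AMIDE else _OH
        f = _segment(p, span) + _H + cterm + _H
    elif kind in ("internal_b", "internal_a"):
        if span[0] <= 1 or span[1] >= n:
            raise FragmentationError("internal spans must touch neither terminus")
        f = _segment(p, span) + _H
        if kind == "internal_a":
            f = f - _CO
    elif kind == "immonium":
        if span[0] != span[1]:
            raise FragmentationError("immonium span must be a single residue")
        f = _segment(p, span) - _CO + _H
    else:
        raise FragmentationError(f"unknown ion kind {kind!r}")

    for loss in sorted(losses):
        try:
            f = f - _LOSS_FORMULAS[loss]
        except KeyError:
            raise FragmentationError(f"unknown neutral loss {loss!r}") from None
    return f.with_charge(+1)


def _label(p: LinearPeptide, kind: str, span: tuple[int, int], losses) -> str:
    n = len(p)
    if kind == "precursor":
        base = "[M+H]+"
    elif kind in ("b", "a"):
        base = f"{kind}{span[1]}"
    elif kind == "y":
        base = f"y{n - span[0] + 1}"
    elif kind in ("internal_b", "internal_a"):
        seq = "-".join(p.residues[span[0] - 1 : span[1]])
        suffix = "-CO" if kind == "internal_a" else ""
        base = f"internal {seq} ({span[0]}-{span[1]}){suffix}"
    else:
        base = f"immonium {p.residues[span[0] - 1]}"
    for loss in sorted(losses):
        base += f" -{loss}"
    return base


def theoretical_ions(
    p: LinearPeptide, cfg: FragmentationConfig | None = None
) -> list[IonSpecies]:
    """Enumerate the deduplicated theoretical ion set of ``p``, sorted by
    m/z descending.  Deterministic for a fixed input."""
    if len(p) < 2:
        raise FragmentationError("fragmentation needs at least two residues")
    cfg = cfg or FragmentationConfig()
    n = len(p)
    loss_sets = cfg.loss_sets()

    wanted: list[tuple[str, tuple[int, int], frozenset[str]]] = []
    if "precursor" in cfg.kinds:
        wanted.append(("precursor", (1, n), frozenset()))
    for j in range(1, n):
        if "b" in cfg.kinds:
            for ls in loss_sets:
                wanted.append(("b", (1, j), ls))
        if "a" in cfg.kinds:
            wanted.append(("a", (1, j), frozenset()))
    for i in range(2, n + 1):
        if "y" in cfg.kinds:
            for ls in loss_sets:
                wanted.append(("y", (i, n), ls))
    for i in range(2, n):
        for j in range(i + cfg.min_internal_length - 1, n):
            if "internal_b" in cfg.kinds:
                for ls in loss_sets:
                    wanted.append(("internal_b", (i, j), ls))
            if "internal_a" in cfg.kinds:
                wanted.append(("internal_a", (i, j), frozenset()))
    if "immonium" in cfg.kinds:
        seen_residues: set[str] = set()
        for k, code in enumerate(p.residues, start=1):
            if code not in seen_residues:
                seen_residues.add(code)
                wanted.append(("immonium", (k, k), frozenset()))

    ions: list[IonSpecies] = []
    seen: set[tuple[str, str, tuple[int, int], frozenset[str]]] = set()
    for kind, span, losses in wanted:
        try:
            f = ion_formula(p, kind, span, losses)
        except (FormulaError, FragmentationError):
            continue  # loss not subtractable from this composition
        key = (f.format(), kind, span, losses)
        if key in seen:
            continue
        seen.add(key)
        ions.append(
            IonSpecies(kind, span, losses, f, f.mass, _label(p, kind, span, losses))
        )
    ions.sort(key=lambda ion: (-ion.mz, ion.kind, ion.span, sorted(ion.losses)))
    return ions


def ion_table_tsv(ions: list[IonSpecies]) -> str:
    """TSV export of a theoretical ion table."""
    lines = ["label\tkind\tspan\tlosses\tformula\ttheoretical_mz"]
    for ion in ions:
        losses = "+".join(sorted(ion.losses)) or "-"
        lines.append(
            f"{ion.label}\t{ion.kind}\t{ion.span[0]}-{ion.span[1]}\t"
            f"{losses}\t{ion.formula.format()}\t{ion.mz:.6f}"
        )
    return "\n".join(lines) + "\n"
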