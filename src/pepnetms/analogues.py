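"""Precursor-delta analogue proposal.

Given a reference peptide and the MS/MS spectrum of a related unknown, the
precursor mass difference is first explained combinatorially (residue
substitutions, terminal-group changes, optional insertions/deletions up to a
complexity cap), then each mass-consistent hypothesis is instantiated at
every compatible sequence position and the resulting candidate structures
are ranked by fragment support: the fraction of the candidate's theoretical
ions found in the unknown spectrum.  Ions whose span does not cover an
edited position coincide with the reference ladder (unshifted match); ions
covering an edit appear at the correspondingly shifted m/z, exactly the
manual fragmentation-pattern comparison used to propose peptide analogues
from networking clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chemformula import MolecularFormula, parse_formula
from .fragments import FragmentationConfig, theoretical_ions
from .peptides import (
    CTerm,
    LinearPeptide,
    NTerm,
    TerminalMods,
    precursor_mz,
    residue_formula,
)
from .spectrum import Spectrum

__all__ = [
    "DeltaHypothesis",
    "AnalogueProposal",
    "AnalogueConfig",
    "FAMILY_ALPHABET",
    "enumerate_delta_hypotheses",
    "apply_hypothesis",
    "propose_analogues",
    "proposals_to_tsv",
]

#: Residue vocabulary observed in the subarmigeride family; a deliberately
#: small default search alphabet (flag up to the full standard set).
FAMILY_ALPHABET: tuple[str, ...] = ("Pro", "Phe", "Xle", "Val")

_CO = parse_formula("CO")
_NH = parse_formula("NH")
_O = parse_formula("O")

#: Terminal edit -> (signed element deltas, requires (n_term or c_term
#: state), resulting state).
_TERMINAL_EDITS = {
    "add_formyl": ({"C": 1, "O": 1}, NTerm.FREE_AMINE, NTerm.FORMYL),
    "remove_formyl": ({"C": -1, "O": -1}, NTerm.FORMYL, NTerm.FREE_AMINE),
    "acid_to_amide": ({"N": 1, "H": 1, "O": -1}, CTerm.FREE_ACID, CTerm.AMIDE),
    "amide_to_acid": ({"N": -1, "H": -1, "O": 1}, CTerm.AMIDE, CTerm.FREE_ACID),
}

_ELEMENT_MASS = {el: parse_formula(el).mass for el in ("C", "H", "N", "O", "S")}


def _delta_counts(f_to: MolecularFormula, f_from: MolecularFormula) -> dict[str, int]:
    out: dict[str, int] = {}
    for el in set(dict(f_to)) | set(dict(f_from)):
        d = f_to[el] - f_from[el]
        if d:
            out[el] = d
    return out


def _counts_mass(counts: dict[str, int]) -> float:
    return sum(_ELEMENT_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class DeltaHypothesis:
    """One combinatorial explanation of a precursor mass difference."""

    substitutions: tuple[tuple[str, str], ...] = ()
    terminal_changes: tuple[str, ...] = ()
    insertions: tuple[str, ...] = ()
    deletions: tuple[str, ...] = ()
    delta_counts: tuple[tuple[str, int], ...] = ()
    delta_mass: float = 0.0

    @property
    def complexity(self) -> int:
        return (
            len(self.substitutions)
            + len(self.terminal_changes)
            + len(self.insertions)
            + len(self.deletions)
        )

    @property
    def is_identity(self) -> bool:
        return self.complexity == 0

    def describe(self) -> str:
        parts = [f"{a}->{b}" for a, b in self.substitutions]
        parts += list(self.terminal_changes)
        parts += [f"+{r}" for r in self.insertions]
        parts += [f"-{r}" for r in self.deletions]
        return " & ".join(parts) if parts else "identity"


@dataclass(frozen=True)
class AnalogueProposal:
    candidate: LinearPeptide
    hypothesis: DeltaHypothesis
    support: float
    edited_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.support <= 1.0):
            raise ValueError("support must lie in [0, 1]")


@dataclass(frozen=True)
class AnalogueConfig:
    precursor_tol_ppm: float = 15.0
    frag_tol_ppm: float = 15.0
    max_edits: int = 2
    alphabet: tuple[str, ...] = FAMILY_ALPHABET
    allow_indels: bool = False
    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)
    max_candidates_per_hypothesis: int = 200


def _moves(alphabet: tuple[str, ...], allow_indels: bool):
    """Elementary edits as (kind, payload, signed element deltas)."""
    moves = []
    for a in alphabet:
        for b in alphabet:
            if a == b:
                continue
            d = _delta_counts(residue_formula(b), residue_formula(a))
            if d:  # isobaric pairs are not distinct edits
                moves.append(("sub", (a, b), d))
    for name, (d, _, _) in _TERMINAL_EDITS.items():
        moves.append(("term", name, dict(d)))
    if allow_indels:
        for r in alphabet:
            moves.append(("ins", r, dict(residue_formula(r))))
            moves.append(("del", r, {el: -n for el, n in residue_formula(r)}))
    return moves


def enumerate_delta_hypotheses(
    delta_mass: float,
    tol_ppm: float = 15.0,
    max_edits: int = 2,
    *,
    ref_mz: float | None = None,
    tol_da: float | None = None,
    alphabet: tuple[str, ...] = FAMILY_ALPHABET,
    allow_indels: bool = False,
) -> list[DeltaHypothesis]:
    """All edit combinations (up to ``max_edits``) whose exact mass matches
    ``delta_mass`` within tolerance, sorted by complexity then closeness.

    The tolerance is ppm relative to the reference precursor when ``ref_mz``
    is given; ``tol_da`` overrides it with an absolute window.  Without
    either, a 0.01 Da window is used.
    """
    if tol_da is None:
        tol_da = tol_ppm * 1e-6 * ref_mz if ref_mz else 0.01

    moves = _moves(tuple(alphabet), allow_indels)
    hypotheses: list[tuple[float, DeltaHypothesis]] = []
    seen = set()

    for n_edits in range(0, max_edits + 1):
        for combo in itertools.combinations_with_replacement(moves, n_edits):
            counts: dict[str, int] = {}
            for _, _, d in combo:
                for el, n in d.items():
                    counts[el] = counts.get(el, 0) + n
            counts = {el: n for el, n in counts.items() if n}
            mass = _counts_mass(counts)
            if abs(mass - delta_mass) > tol_da:
                continue
            subs = tuple(sorted(p for k, p, _ in combo if k == "sub"))
            terms = tuple(sorted(p for k, p, _ in combo if k == "term"))
            ins = tuple(sorted(p for k, p, _ in combo if k == "ins"))
            dels = tuple(sorted(p for k, p, _ in combo if k == "del"))
            key = (subs, terms, ins, dels)
            if key in seen:
                continue
            seen.add(key)
            hyp = DeltaHypothesis(
                substitutions=subs,
                terminal_changes=terms,
                insertions=ins,
                deletions=dels,
                delta_counts=tuple(sorted(counts.items())),
                delta_mass=mass,
            )
            hypotheses.append((abs(mass - delta_mass), hyp))

    hypotheses.sort(key=lambda t: (t[1].complexity, t[0], t[1].describe()))
    return [h for _, h in hypotheses]


def apply_hypothesis(
    reference: LinearPeptide, hyp: DeltaHypothesis, max_candidates: int = 200
) -> list[tuple[LinearPeptide, tuple[int, ...]]]:
    """Instantiate a hypothesis at every compatible position combination.

    Returns ``(candidate, edited_positions)`` pairs (1-based positions;
    terminal changes contribute no position).  Substitution positions are
    matched on the Xle-collapsed sequence.  An empty list means the
    hypothesis is structurally incompatible with the reference (e.g.
    ``remove_formyl`` on a free amine).
    """
    ref = reference.collapse_xle()
    mods = ref.mods
    for name in hyp.terminal_changes:
        _, requires, becomes = _TERMINAL_EDITS[name]
        if isinstance(requires, NTerm):
            if mods.n_term is not requires:
                return []
            mods = TerminalMods(becomes, mods.c_term)
        else:
            if mods.c_term is not requires:
                return []
            mods = TerminalMods(mods.n_term, becomes)

    # position choices for each substitution (distinct positions overall)
    slot_options: list[list[int]] = []
    for frm, _ in hyp.substitutions:
        slots = [i for i, r in enumerate(ref.residues) if r == frm]
        if not slots:
            return []
        slot_options.append(slots)

    out: list[tuple[LinearPeptide, tuple[int, ...]]] = []
    seen: set[tuple] = set()
    for placement in itertools.product(*slot_options) if slot_options else [()]:
        if len(set(placement)) != len(placement):
            continue
        residues = list(ref.residues)
        for (frm, to), pos in zip(hyp.substitutions, placement):
            residues[pos] = to
        base_positions = tuple(sorted(p + 1 for p in placement))
        variants: list[tuple[tuple[str, ...], tuple[int, ...]]]
        variants = [(tuple(residues), base_positions)]

        for r in hyp.deletions:
            new_variants = []
            for seq, pos in variants:
                for i, code in enumerate(seq):
                    if code == r:
                        new_variants.append((seq[:i] + seq[i + 1 :], pos + (i + 1,)))
            variants = new_variants
        for r in hyp.insertions:
            new_variants = []
            for seq, pos in variants:
                for i in range(len(seq) + 1):
                    new_variants.append(
                        (seq[:i] + (r,) + seq[i:], pos + (i + 1,))
                    )
            variants = new_variants

        for seq, positions in variants:
            if not seq:
                continue
            key = (seq, mods.n_term, mods.c_term)
            if key in seen:
                continue
            seen.add(key)
            cand = LinearPeptide(seq, mods, name=f"{reference.name or 'ref'}~{hyp.describe()}")
            out.append((cand, positions))
            if len(out) >= max_candidates:
                return out
    return out


def _support(
    candidate: LinearPeptide,
    unknown: Spectrum,
    frag_tol_ppm: float,
    cfg: FragmentationConfig,
) -> float:
    """Fraction of the candidate's theoretical ions with a matching peak."""
    ions = theoretical_ions(candidate, cfg)
    if not ions or not unknown.peaks:
        return 0.0
    peak_mzs = unknown.mz_array
    ion_mzs = np.array([ion.mz for ion in ions])
    idx = np.searchsorted(peak_mzs, ion_mzs)
    matched = 0
    for k, mz in enumerate(ion_mzs):
        tol = frag_tol_ppm * 1e-6 * mz
        for j in (idx[k] - 1, idx[k]):
            if 0 <= j < len(peak_mzs) and abs(peak_mzs[j] - mz) <= tol:
                matched += 1
                break
    return matched / len(ions)


def propose_analogues(
    reference: LinearPeptide,
    unknown: Spectrum,
    cfg: AnalogueConfig | None = None,
) -> list[AnalogueProposal]:
    """Rank candidate structures for ``unknown`` relative to ``reference``.

    Support is computed on the unknown's peak positions only, so it is
    invariant to intensity scaling.  Proposals are sorted by support
    descending, then hypothesis complexity, then notation (deterministic).
    An empty list means no hypothesis matched the precursor delta.
    """
    cfg = cfg or AnalogueConfig()
    ref_mz = precursor_mz(reference)
    delta = unknown.precursor_mz - ref_mz
    hypotheses = enumerate_delta_hypotheses(
        delta,
        tol_ppm=cfg.precursor_tol_ppm,
        ref_mz=unknown.precursor_mz,
        max_edits=cfg.max_edits,
        alphabet=cfg.alphabet,
        allow_indels=cfg.allow_indels,
    )

    proposals: list[AnalogueProposal] = []
    for hyp in hypotheses:
        for cand, positions in apply_hypothesis(
            reference, hyp, cfg.max_candidates_per_hypothesis
        ):
            support = _support(cand, unknown, cfg.frag_tol_ppm, cfg.fragmentation)
            proposals.append(AnalogueProposal(cand, hyp, support, positions))

    proposals.sort(
        key=lambda p: (
            -p.support,
            p.hypothesis.complexity,
            p.candidate.notation(),
        )
    )
    return proposals


def proposals_to_tsv(proposals: list[AnalogueProposal]) -> str:
    lines = ["rank\thypothesis\tedited_positions\tsupport\tcandidate"]
    for rank, p in enumerate(proposals, start=1):
        pos = ",".join(map(str, p.edited_positions)) or "-"
        lines.append(
            f"{rank}\t{p.hypothesis.describe()}\t{pos}\t{p.support:.3f}\t"
            f"{p.candidate.notation()}"
        )
    return "\n".join(lines) + "\n"
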