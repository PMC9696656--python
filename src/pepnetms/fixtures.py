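"""The subarmigeride compound family A-H as reusable fixtures.

Notations are given in the published amide-end-first orientation ("NH2-"
marks the C-terminal primary amide; a trailing "-CHO"/"-COOH" the N-terminal
formyl/carboxyl group) and are parsed to canonical N-to-C peptides.
Leu/Ile positions of the putative analogues B-H are mass-ambiguous and are
stored as Xle; compound A's leucines were fixed by NMR and keep their codes.

Reference values (observed [M+H]+ m/z and printed cation formulas) are the
published ones.  Note on compound F: the published formula string
C40H63N7O8 implies a half-integer DBE and cannot belong to an even-electron
peptide cation; the free-acid form of compound E, C40H62N7O8+, matches the
published observed m/z within 0.6 ppm and is used here (the one-hydrogen
difference is treated as a typographical error, flagged in the manifest).
"""

from __future__ import annotations

from .peptides import LinearPeptide, parse_sequence_notation, precursor_formula, precursor_mz
from .simulate import SimulatedSpectrum, SimulationConfig, derive_subseed, simulate_spectrum
from .spectrum import Spectrum

__all__ = [
    "FAMILY_NOTATIONS",
    "PRINTED_PRECURSOR_MZ",
    "PRINTED_FORMULAS",
    "FLAGGED_ROWS",
    "subarmigeride",
    "fixture_peptides",
    "generate_fixture_set",
    "fixture_manifest_tsv",
]

#: Published sequence notations, amide-end first.
FAMILY_NOTATIONS: dict[str, str] = {
    "A": "NH2-Leu-Pro-Pro-Phe-Phe-Pro-Leu-CHO",
    "B": "NH2-Leu/Ile-Pro-Pro-Phe-Pro-Leu/Ile-Leu/Ile-CHO",
    "C": "NH2-Leu/Ile-Pro-Pro-Phe-Leu/Ile-Pro-Leu/Ile-COOH",
    "D": "NH2-Leu/Ile-Pro-Pro-Phe-Phe-Pro-Leu/Ile",
    "E": "NH2-Leu/Ile-Pro-Pro-Phe-Pro-Val-Val",
    "F": "Leu/Ile-Pro-Pro-Phe-Pro-Val-Val",
    "G": "NH2-Leu/Ile-Pro-Pro-Phe-Leu/Ile-Leu/Ile-Val-Pro-COOH",
    "H": "NH2-Leu/Ile-Pro-Pro-Phe-Pro-Val-Val-CHO",
}

#: Published observed [M+H]+ m/z per compound.
PRINTED_PRECURSOR_MZ: dict[str, float] = {
    "A": 857.4914,
    "B": 823.5078,
    "C": 839.5024,
    "D": 829.4962,
    "E": 767.4807,
    "F": 768.4650,
    "G": 938.5698,
    "H": 795.4763,
}

#: Published [M+H]+ cation formula strings (charge sign omitted).
PRINTED_FORMULAS: dict[str, str] = {
    "A": "C46H65N8O8",
    "B": "C43H67N8O8",
    "C": "C43H67N8O9",
    "D": "C45H65N8O7",
    "E": "C40H63N8O7",
    "F": "C40H63N7O8",  # typographical: see module docstring and FLAGGED_ROWS
    "G": "C48H76N9O10",
    "H": "C41H63N8O8",
}

#: Rows whose published annotation is internally inconsistent, with the
#: reading adopted here.
FLAGGED_ROWS: dict[str, str] = {
    "C": "terminal labels read as C-amide + N-carboxyl (+CO2); this is the "
         "only reading that reproduces the published formula C43H67N8O9+",
    "F": "published formula C40H63N7O8+ has non-integer DBE; computed "
         "C40H62N7O8+ (acid form of E) matches the published m/z to 0.6 ppm",
    "G": "terminal labels read as C-amide + N-carboxyl (+CO2), as for C",
}


def subarmigeride(name: str) -> LinearPeptide:
    """One of the family peptides, canonical N-to-C storage."""
    try:
        notation = FAMILY_NOTATIONS[name]
    except KeyError:
        raise KeyError(f"unknown compound {name!r}; expected A-H") from None
    p = parse_sequence_notation(notation, family_convention=True)
    return LinearPeptide(p.residues, p.mods, name=f"subarmigeride_{name}")


def fixture_peptides() -> dict[str, LinearPeptide]:
    return {name: subarmigeride(name) for name in FAMILY_NOTATIONS}


def generate_fixture_set(
    seed: int, cfg: SimulationConfig | None = None, as_spectra: bool = False
) -> list[SimulatedSpectrum] | list[Spectrum]:
    """One simulated spectrum per compound A-H, per-compound sub-seeds
    derived from ``seed`` by stable name hashing."""
    out = []
    for name, peptide in fixture_peptides().items():
        base = cfg or SimulationConfig(seed=0)
        sub = SimulationConfig(
            **{
                **{f: getattr(base, f) for f in base.__dataclass_fields__},
                "seed": derive_subseed(seed, f"subarmigeride_{name}"),
            }
        )
        out.append(simulate_spectrum(peptide, sub, f"subarmigeride_{name}"))
    if as_spectra:
        return [sim.spectrum for sim in out]
    return out


def fixture_manifest_tsv() -> str:
    """Manifest: name, notation, computed neutral formula and [M+H]+ m/z,
    published observed m/z, flags."""
    from .peptides import neutral_formula

    lines = [
        "name\tnotation\tneutral_formula\tcomputed_mh_formula\t"
        "computed_mh_mz\tprinted_mz\tflag"
    ]
    for name in FAMILY_NOTATIONS:
        p = subarmigeride(name)
        lines.append(
            f"{name}\t{FAMILY_NOTATIONS[name]}\t"
            f"{neutral_formula(p).format()}\t"
            f"{precursor_formula(p).format(include_charge=False)}\t"
            f"{precursor_mz(p):.4f}\t{PRINTED_PRECURSOR_MZ[name]:.4f}\t"
            f"{FLAGGED_ROWS.get(name, '-')}"
        )
    return "\n".join(lines) + "\n"
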