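"""ppm-tolerance matching of observed peaks to theoretical ions.

Covers product-ion table generation (peak -> ion assignments with signed ppm
errors), residue detection from immonium ions, and residue-ladder sequence
tag extraction from consecutive peak mass differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemformula import parse_formula, ppm_error
from .fragments import FragmentationConfig, IonSpecies, theoretical_ions
from .peptides import (
    RESIDUE_FORMULAS,
    LinearPeptide,
    residue_formula,
    residue_mass,
)
from .spectrum import Peak, Spectrum

__all__ = [
    "AnnotationRecord",
    "SequenceTag",
    "annotate_spectrum",
    "residues_from_immonium",
    "extract_sequence_tags",
    "write_annotation_table",
]

#: Tie-break priority when several ions sit at the same |ppm| from a peak:
#: primary backbone ions first, loss satellites late, immonium last.
_KIND_PRIORITY = {
    "precursor": 0,
    "b": 1,
    "y": 2,
    "a": 3,
    "internal_b": 4,
    "internal_a": 5,
    "immonium": 7,
}
_SATELLITE_PRIORITY = 6


def _ion_priority(ion: IonSpecies) -> tuple:
    rank = _SATELLITE_PRIORITY if ion.losses else _KIND_PRIORITY[ion.kind]
    return (rank, len(ion.losses), _KIND_PRIORITY[ion.kind], ion.span)


@dataclass(frozen=True)
class AnnotationRecord:
    peak: Peak
    ion: IonSpecies
    error_ppm: float


@dataclass(frozen=True)
class SequenceTag:
    """A maximal residue ladder read off consecutive peak differences.

    ``residues`` are listed in descending-anchor order; for a y-ion ladder
    that reading runs N-to-C, for a b-ion ladder C-to-N (the ion series is
    unknown at extraction time, so ``direction`` records the reported
    orientation of the listing, not a structural claim).
    """

    residues: tuple[str, ...]
    anchors: tuple[float, ...]
    direction: str = "n_to_c"


def annotate_spectrum(
    s: Spectrum,
    p: LinearPeptide,
    tol_ppm: float = 15.0,
    cfg: FragmentationConfig | None = None,
) -> tuple[list[AnnotationRecord], list[Peak]]:
    """Match peaks to theoretical ions of ``p`` within ``tol_ppm``.

    Matching is injective (one ion per peak and vice versa), assigned
    greedily by ascending |ppm| with deterministic tie-breaking (primary
    backbone ions preferred, then shorter loss sets).  Returns the records
    sorted by m/z descending and the unmatched peaks unaltered.

    The default tolerance of 15 ppm is deliberately wider than the 10 ppm
    used for MS1 feature matching: the reference product-ion table for this
    peptide family itself contains an 11.2 ppm assignment.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    ions = theoretical_ions(p, cfg)

    candidates = []
    for ion_idx, ion in enumerate(ions):
        half = tol_ppm * 1e-6 * ion.mz
        for peak_idx, peak in enumerate(s.peaks):
            if abs(peak.mz - ion.mz) <= half:
                err = ppm_error(ion.mz, peak.mz)
                candidates.append(
                    (abs(err), _ion_priority(ion), ion_idx, peak_idx, err)
                )
    candidates.sort()

    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    records: list[AnnotationRecord] = []
    for _, _, ion_idx, peak_idx, err in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
        records.append(AnnotationRecord(s.peaks[peak_idx], ions[ion_idx], err))

    records.sort(key=lambda r: -r.peak.mz)
    unmatched = [pk for i, pk in enumerate(s.peaks) if i not in used_peaks]
    return records, unmatched


def _immonium_mz(code: str) -> float:
    f = (residue_formula(code) - parse_formula("CO") + parse_formula("H")).with_charge(+1)
    return f.mass


def residues_from_immonium(s: Spectrum, tol_ppm: float = 15.0) -> set[str]:
    """Residue codes whose immonium ion matches some peak within tolerance.
    Leu/Ile are reported as the mass-ambiguous Xle."""
    if not s.peaks:
        return set()
    mzs = s.mz_array
    found: set[str] = set()
    for code in RESIDUE_FORMULAS:
        if code in ("Leu", "Ile"):
            continue  # collapsed into Xle
        imm = _immonium_mz(code)
        if np.any(np.abs(mzs - imm) <= tol_ppm * 1e-6 * imm):
            found.add(code)
    return found


def _step_masses(include_modified: bool) -> dict[str, float]:
    steps = {
        code: residue_mass(code)
        for code in RESIDUE_FORMULAS
        if code not in ("Leu", "Ile")
    }
    if include_modified:
        co = parse_formula("CO").mass
        for code in list(steps):
            steps[f"CHO-{code}"] = steps[code] + co
    return steps


def extract_sequence_tags(
    s: Spectrum,
    tol_ppm: float = 15.0,
    min_len: int = 2,
    include_modified: bool = False,
) -> list[SequenceTag]:
    """All maximal chains of peaks whose successive m/z differences equal a
    residue mass within tolerance (absolute tolerance taken at the heavier
    anchor, consistent with instrument-relative accuracy).

    ``min_len`` counts residues, i.e. a tag of ``min_len`` spans
    ``min_len + 1`` anchor peaks.  ``include_modified`` additionally allows
    formylated first-residue steps (residue + CO), which bridge a precursor
    to the first backbone fragment of an N-formylated peptide.
    """
    mzs = sorted((p.mz for p in s.peaks), reverse=True)
    steps = _step_masses(include_modified)

    # edges[i] = list of (j, code) reachable one residue down from anchor i
    edges: list[list[tuple[int, str]]] = [[] for _ in mzs]
    has_incoming = [False] * len(mzs)
    for i, hi in enumerate(mzs):
        tol_abs = tol_ppm * 1e-6 * hi
        for j in range(i + 1, len(mzs)):
            diff = hi - mzs[j]
            best = None
            for code, m in steps.items():
                dev = abs(diff - m)
                if dev <= tol_abs and (best is None or dev < best[1]):
                    best = (code, dev)
            if best is not None:
                edges[i].append((j, best[0]))
                has_incoming[j] = True

    tags: list[SequenceTag] = []

    def walk(idx: int, residues: list[str], anchors: list[float]):
        if not edges[idx]:
            if len(residues) >= min_len:
                tags.append(SequenceTag(tuple(residues), tuple(anchors)))
            return
        for j, code in edges[idx]:
            walk(j, residues + [code], anchors + [mzs[j]])

    for i in range(len(mzs)):
        if not has_incoming[i] and edges[i]:
            walk(i, [], [mzs[i]])

    tags.sort(key=lambda t: (-len(t.residues), -t.anchors[0]))
    return tags


def write_annotation_table(records: list[AnnotationRecord]) -> str:
    """Product-ion table as TSV: assignment label, observed m/z (6 dp),
    error in ppm (1 dp), cation formula (charge sign omitted, as in
    published product-ion tables)."""
    lines = ["assignment\tobserved_mz\terror_ppm\tformula"]
    for r in records:
        lines.append(
            f"{r.ion.label}\t{r.peak.mz:.6f}\t{r.error_ppm:.1f}\t"
            f"{r.ion.formula.format(include_charge=False)}"
        )
    return "\n".join(lines) + "\n"
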