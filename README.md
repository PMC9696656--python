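# pepnetms

Exact-mass MS/MS annotation, analogue inference and molecular networking for
terminally modified linear peptides.

`pepnetms` implements the computational chain by which an unusual linear
heptapeptide family — N-formylated, C-terminally amidated peptides built from
Pro/Phe/Leu(Ile)/Val, exemplified by subarmigeride A
(`CHO-Leu-Pro-Phe-Phe-Pro-Pro-Leu-NH2`, [M+H]⁺ ≈ 857.49) — can be elucidated
and dereplicated from tandem mass spectra alone:

1. **Formula arithmetic** — molecular formulas as exact element-count maps;
   monoisotopic masses from pinned CODATA atomic masses with electron-mass
   correction for cations; degrees of unsaturation (DBE = C − H/2 + N/2 + 1);
   signed ppm errors ((calc − obs)/calc × 10⁶).
2. **Peptide model** — linear peptides with N-terminal free amine / formyl
   (+CO) / carboxyl (+CO₂) and C-terminal free acid / primary amide
   (−O +NH) states, parsed from either sequence-notation orientation.
3. **Fragment enumeration** — singly protonated b/a/y ions, internal b/a
   ions, immonium ions and −NH₃/−CO satellites: for the reference
   heptapeptide this ion set explains all 28 published product ions within
   a few ppm.
4. **Annotation** — injective ppm-tolerance peak→ion matching, immonium
   residue detection, and residue-ladder sequence-tag extraction.
5. **Analogue inference** — explains a precursor mass difference as residue
   substitutions and/or terminal-group edits, instantiates candidates at
   every compatible position, and ranks them by how much of the candidate's
   fragment ladder is present (shifted or unshifted) in the unknown
   spectrum.
6. **Spectral networking** — modified-cosine similarity (√-intensity, L2
   normalization, greedy one-to-one pairing with precursor-shifted matches),
   molecular-family graphs at cosine ≥ 0.65 / > 6 matched peaks / mutual
   top-10, and a MASST-style filtered library search (±17 Da precursor
   exclusion, top-6 per ±50 Da window, 2.0/0.5 Da tolerances).
7. **Synthetic spectra** — a seeded generator of realistic singly protonated
   peptide MS/MS spectra (few-ppm Gaussian mass error, lognormal intensity
   jitter, Poisson noise peaks) plus strict MGF I/O, standing in for raw
   LC-MS/MS data that is not publicly deposited.

It is intended for natural-product and peptidomics researchers who want a
reproducible, scriptable version of the usual manual workflow: assign a
product-ion table, read residue content off immonium ions and mass ladders,
propose putative analogues from networking clusters, and search spectra
against a library.

## Worked example

```python
from pepnetms import *

p = parse_sequence_notation("CHO-Leu-Pro-Phe-Phe-Pro-Pro-Leu-NH2")
print("neutral:", neutral_formula(p).format(), " DBE:", int(dbe(neutral_formula(p))))
print("[M+H]+ :", precursor_formula(p).format(), f"{precursor_mz(p):.4f}")

s = Spectrum("obs", 857.4914, peaks=(
    Peak(716.4146, 1.0), Peak(630.3298, 1.0),
    Peak(239.1387, 1.0), Peak(70.0645, 1.0),
))
records, unmatched = annotate_spectrum(s, p, tol_ppm=15)
print(write_annotation_table(records))
```

prints

```
neutral: C46H64N8O8  DBE: 19
[M+H]+ : C46H65N8O8+ 857.4920
assignment	observed_mz	error_ppm	formula
y6	716.414600	-2.2	C39H54N7O6
b5	630.329800	-1.9	C35H44N5O6
b2	239.138700	1.3	C12H19N2O3
immonium Pro	70.064500	8.9	C4H8N
```

i.e. the heptapeptide's neutral formula carries 19 ring-plus-double-bond
equivalents, its calculated [M+H]⁺ is 857.4920, and the four observed peaks
are assigned to the C-terminal y6 ion, two N-terminal b ions (which carry
the formyl group) and the proline immonium ion, each with its signed ppm
error.

From the shell, the same machinery drives five subcommands:

```sh
pepnetms simulate --seed 42 --out family.mgf          # 8-compound family
pepnetms annotate --mgf family.mgf --peptide "CHO-Leu-Pro-Phe-Phe-Pro-Pro-Leu-NH2"
pepnetms network  --mgf family.mgf --out net          # edges TSV + GraphML
pepnetms propose  --reference "CHO-Leu-Pro-Phe-Phe-Pro-Pro-Leu-NH2" --mgf family.mgf
pepnetms masst    --mgf family.mgf --library family.mgf
```

`network` reports a single 8-node connected component for the simulated
family at the default thresholds, and `propose` recovers, e.g., the
`remove_formyl` hypothesis for the des-formyl analogue.

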