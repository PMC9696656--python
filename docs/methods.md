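# Methods

## Scope and model

`pepnetms` models singly protonated linear peptides and their tandem mass
spectra.  The chemistry is deliberately minimal: the 20 standard residues
plus Xle (the Leu/Ile composition C6H11NO — MS cannot distinguish the two,
so strict comparisons collapse both to Xle), an N-terminal state of free
amine, formyl (+CO) or carboxyl (+CO₂), and a C-terminal state of free acid
or primary amide (−O +NH relative to the acid).  Multiply charged species,
side-chain modifications, cyclic peptides, isotope envelopes and
stereochemistry are out of scope.

A peptide's neutral composition is the residue sum plus H₂O plus the
terminal-state deltas.  All masses are monoisotopic, from pinned constants:
C 12 (exact), H 1.00782503207, N 14.0030740048, O 15.9949146196,
S 31.97207117, electron 0.00054857991 Da.  A cation's m/z subtracts one
electron mass from its composition mass rather than adding a rounded proton
shortcut; at QTOF accuracy the difference is visible in the fourth decimal.
With these constants the recomputed ppm errors of all 28 published product
ions of the reference heptapeptide agree with the published error column
within ±0.3 ppm, and the calculated [M+H]⁺ is 857.49199 vs the published
calcd 857.4919 (the authors' constant set is unstated; agreement is within
0.0002 Da).

The ppm error convention is (calculated − observed)/calculated × 10⁶ — the
only sign convention consistent with the published product-ion table.

## Sequence-notation orientation

The family is written in two orientations in the literature:
`CHO-Leu-…-Leu-NH2` (N→C) and `NH2-Leu-…-Leu-CHO` (amide end first).  NMR
evidence fixes the chemistry — formyl on the backbone nitrogen of the last
written residue in the second form — so the parser treats a *trailing*
`-CHO`/`-COOH` token as marking an amide-end-first string and reverses it
into canonical N→C storage.  Under this reading, the published analogue
table is internally consistent: its des-formyl row is literally the
reference sequence minus CO in the same residue order, and the rows with a
trailing `-COOH` reproduce their published cation formulas exactly when
that token is read as an N-terminal carboxyl (+CO₂) together with the
family's C-amide.  One published analogue formula (compound F,
C40H63N7O8⁺) implies a half-integer DBE and cannot be an even-electron
peptide cation; the computed acid form of compound E (C40H62N7O8⁺) matches
the published observed m/z to 0.6 ppm and is adopted, with the
one-hydrogen discrepancy flagged in the fixture manifest.

## Fragment ions

Enumerated kinds (all +1 cations): precursor [M+H]⁺; b (residues 1..i,
i < N; the N-terminal cap — H, H+CO or H+CO₂ — travels with the series);
a = b − CO; y (residues i..N, i > 1; carries NH₂ for amides, OH for acids,
plus the proton); internal b-type (Σ residues + H, spans touching neither
terminus, length ≥ 2 by default); internal a-type = internal b − CO;
immonium (residue − CO + H).  Neutral-loss satellites −NH₃ and −CO (each at
most once, combinable) are offered on b, y and internal b ions; a-type ions
have already lost CO and take no further CO loss.  This is the minimal set
that explains every row of the reference product-ion table (28/28 printed
formulas generated).

Internal spans are restricted to touch neither terminus because spans
ending at the last residue are formula-identical to y − NH₃ satellites and
would only duplicate compositions.  Formula isomerism still exists (a1 vs
immonium of residue 1 on unmodified peptides; a_{N−1} vs y_{N−1} − NH₃ on
the formylated amide): deduplication is therefore by (formula, kind, span,
losses), and annotation tie-breaking resolves the rest.

## Annotation

Peak→ion matching is injective, assigned greedily by ascending |ppm|, with
deterministic tie-breaking: precursor > b > y > a > internal b > internal a
> loss satellites > immonium, then fewer losses.  The default tolerance is
15 ppm — wider than the 10 ppm used for MS1 feature matching — because the
reference product-ion table itself contains an 11.2 ppm assignment; it is a
parameter everywhere.  Sequence tags chain peaks whose successive
differences equal residue masses, with the absolute tolerance taken at the
heavier anchor (instrument accuracy is relative); maximal chains are
reported longest first.  An optional extension allows formylated
first-residue steps (residue + CO), which bridge the precursor to the first
backbone fragment of N-formylated peptides.

## Analogue inference

The precursor delta between an unknown and the reference is explained by
combinations of elementary edits (residue substitutions over a configurable
alphabet, the four terminal changes add/remove formyl and amide↔acid,
optionally indels) up to a complexity cap of 2.  The search alphabet
defaults to the residues observed in the family (Pro, Phe, Xle, Val) to
keep the hypothesis space honest and small; the full standard set is a
flag.  Each mass-consistent hypothesis is instantiated at every compatible
position; a candidate's support is the fraction of its theoretical ions
found among the unknown's peaks at fragment ppm tolerance.  Because
candidate ions coincide with reference ions wherever no edited position is
covered, this is exactly the "shifted vs unshifted ladder" comparison done
manually, but positional placement is scored rather than assumed — for
analogues whose published residue order is a rearrangement of the
reference, a multi-edit positional hypothesis can (correctly) outrank the
net-composition single swap.  Support depends only on peak positions, so it
is invariant to intensity scaling.

## Spectral similarity and networking

Modified cosine: intensities are square-root transformed and
L2-normalized; candidate peak pairs match within the fragment tolerance
either directly or offset by the precursor mass difference; a one-to-one
pairing is selected greedily by descending intensity product (the
convention of public networking infrastructure).  Greedy pairing is not
provably optimal, but on 200 seeded random instances with ≤ 8 peaks it
equals the exhaustive maximum-weight matching, and an independent
implementation (matchms `ModifiedCosine`) reproduces both score and match
count on family and random spectra to 1e-6.  Symmetry is guaranteed by
computing in a canonical argument order.

Networks: all-pairs modified cosine at 0.02 Da; edges kept at cosine ≥ 0.65
and ≥ 7 matched peaks ("more than 6"); an edge survives only if each
endpoint is in the other's top 10 most similar nodes (ties broken by id).
The library search prefilters query and library identically (peaks within
±17 Da of the precursor removed; each peak kept only if among the 6 most
intense in its ±50 Da window — an idempotent filter), restricts candidates
to ±2.0 Da precursor, scores at 0.5 Da fragment tolerance, and keeps
matches with score > 0.2 and ≥ 3 matched peaks.

## Synthetic spectra

The generator renders a peptide's theoretical ion set with ion-kind base
intensities (y 1.0, b 0.8, precursor 0.7, immonium 0.6, internal b 0.5,
a 0.4, internal a 0.3; ×0.3 per neutral loss), multiplies by lognormal
jitter (σ = 0.2), perturbs every m/z by zero-mean Gaussian ppm error
(σ = 3 ppm, matching the 0–11 ppm deviations of the published table), and
adds Poisson(5) noise peaks uniform in [50 Da, precursor − 20 Da] with
intensity ≤ 5 % of the base peak.  The intensity scale is
arbitrary-but-fixed: true relative intensities for this compound class are
unpublished, so nothing downstream asserts intensity values.  A master seed
expands to per-compound sub-seeds by stable hashing of the compound name,
so adding a compound never perturbs the others; identical
(peptide, config, seed) yields byte-identical MGF output.

What the generator does *not* emulate: intensity structure (mobile-proton
effects, rank correlations), isotope clusters, adducts, chimeric spectra,
chromatographic context, and detector saturation.  Passing tests therefore
demonstrate correctness of the m/z-level reasoning chain under realistic
mass error — not robustness to every artefact of real LC-MS/MS data.

## Problem sizes and numerical choices

Tests run the full 8-compound family (~80–130 peaks per spectrum), 100
seeded trials per planted-edit recovery experiment, 200 random instances
for the pairing oracle and 100 for prefilter idempotence; the whole suite
completes in well under a minute.  The original study's 56-node sponge
cluster is not reproducible because the raw data are not deposited; the
property-based surrogate (8 related + 3 unrelated synthetic spectra,
seed 42) stands in for it.  Peaks closer than 1e-6 Da are merged on
spectrum construction; records and reports are deterministically ordered;
all thresholds ("above 0.65", "more than 6", "at least 3") follow the
literal published reading (≥ 0.65 is used for the cosine cut, matching
common networking practice).

## Known limitations

* Leu/Ile (and other isobaric/isomeric assignments) are inherently
  unresolved; reports use Xle.
* Support scoring weights all ion kinds equally; with very sparse spectra
  the identity hypothesis can tie with low-support alternatives (ties are
  broken by complexity, favouring simpler structures).
* The greedy pairing can in principle differ from the optimal assignment on
  adversarial dense spectra; the brute-force oracle bounds this only on
  small instances.
* The N-terminal carboxyl state is a formula-level reading of the published
  "-COOH" terminal labels; no claim is made about its chemical stability.
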