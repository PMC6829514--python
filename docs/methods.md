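# Methods

## Cleavage-rule semantics

A cleavage site is a peptide bond, indexed by the 1-based position of its
N-terminal residue (site *i* joins residues *i* and *i*+1; valid sites lie
in [1, L−1]). Specificity is declared positionally: `p1_allow` triggers on
the residue N-terminal of the bond, `p2_allow` (used for papain's
"residues following phenylalanine" behaviour) triggers one position
further upstream, `p1_block` vetoes the trigger, and `p1prime_allow` /
`p1prime_block` constrain the residue C-terminal of the bond — the classic
proline exception is `p1prime_block: P`. Allow and block sets for the same
position must be disjoint; a bond with no P2 (the first bond of a chain)
cannot satisfy a P2 trigger. Site firing is per-bond and independent, so
no tie-breaking is ever needed.

Because no machine-readable specificity accompanies most prose
descriptions of food-grade proteases, the bundled table is an editorial
reconstruction of Keil/PeptideCutter-style conventions:

| enzyme | EC | rule |
|---|---|---|
| pepsin_ph_gt2 | 3.4.23.1 | P1 ∈ {F, L, W, Y, E}, P1′ ≠ P |
| bromelain_stem | 3.4.22.32 | P1 ∈ {K, R, A, Y, G}, P1′ ≠ P |
| papain | 3.4.22.2 | P1 ∈ {K, R} or P2 = F, P1′ ≠ P |
| trypsin | 3.4.21.4 | P1 ∈ {K, R}, P1′ ≠ P |
| chymotrypsin_a | 3.4.21.1 | P1 ∈ {F, Y, W}, P1′ ≠ P |
| lys_c | 3.4.21.50 | P1 = K |

Pepsin's documented refusal to cut at V, A and G is honoured implicitly —
those residues are simply absent from its allow set — rather than encoded
as a block list, which keeps allow/block disjointness trivially true. Stem
bromelain is the lowest-confidence entry: its published specificity
concerns small synthetic substrates, not proteins, so the broad
basic/small-residue convention used here should be overridden by users
with better information. The whole table is versioned
(`peptikit-rules-1.0`), stamped into every report and manifest, and
replaceable entry-by-entry via YAML config; results are therefore always
attributable to a declared rule table rather than to a remote service
whose rules may change.

## Digestion

Complete digestion (every fireable bond cut) is the default and matches
how hosted "enzyme action" simulators behave; the zero-missed fragments
partition the parent, which is both an invariant and a test. Missed
cleavages exist for MS-support use cases: with `max_missed = m`, every run
of at most m+1 consecutive zero-missed fragments is additionally emitted
with its internal-site count, so with k sites exactly k+1−j fragments
carry `n_missed = j`. Sequential multi-enzyme digestion is implemented as
a single cut at the union of the site sets — with complete digestion the
order of application provably cannot matter, and the union form makes the
monotonicity property (each enzyme's sites are a subset of the output
cuts) directly testable. Kinetic or partial digestion (real hydrolysates
reach degrees of hydrolysis around 18–22%, far from completeness) is
deliberately out of scope; the simulator answers "what could this enzyme
release", not "what did it release in 4 h".

## Profiling and counting

The activity profile enumerates substrings only up to the catalogue's
maximum entry length (entries are typically 2–12 residues), so profiling
is O(L · max_len) dictionary lookups rather than O(L²). Counts are
occurrence counts: overlapping matches and repeated instances each count
once. This is the only convention consistent with the large per-protein
hit totals that hosted-database profiles report, but a distinct-peptide
mode (`distinct=True`, CLI `--distinct`) is provided because some
released-fragment reports deduplicate; every report row labels its
counting mode. The main interpretive choice of the package is that
"search for active fragments" matches **whole released fragments** only: a
released 10-mer that merely contains a bioactive dipeptide is not a hit,
because the dipeptide was not itself released. The consequence — digests
always score at most as high as the parent profile, activity by activity —
is asserted as a property test. Single-residue catalogue entries are
excluded by default (`min_len = 2`) since free amino acids are not
peptides; this is configurable.

## Mass arithmetic

Monoisotopic and average residue masses are pinned in the source at six
decimals, with water 18.010565 Da and proton 1.007276 Da, so that printed
2-decimal masses are bit-stable across platforms and library versions;
the table is cross-checked against pyteomics in the test suite (to 1e-3,
the tolerance at which the two constants tables agree). m/z assumes
protonation only — no adducts, no modifications. Observed instrument
signals can differ from these theoretical values by isotope selection or
unresolved modifications; the package computes theory and leaves
observed-vs-theoretical judgement to the user.

## Assay formulas and their boundaries

The three formulas are pure arithmetic on validated readout containers.
Readout validation distinguishes fatal inconsistencies (total amino groups
not exceeding time-zero; a zero control slope; identical positive and
negative controls) from suspicious-but-possible measurements (free amino
groups above the acid-hydrolysis total; computed inhibition outside
[0, 100]), which warn and proceed — clamping or rejecting them would hide
assay problems from the analyst. IER is a plain quotient and inherits its
inputs' uncertainty; it is undefined at zero peptide content. OPA
quantification uses unweighted ordinary least squares (scipy's
`linregress`) with R² reported and out-of-range samples flagged as
extrapolations; weighted schemes are out of scope.

## Synthetic data: what it emulates, what it does not

The generator emulates the *shape* of a hydrolysate-screening study: five
proteins of 150–1900 residues (the span of a myofibrillar panel from
regulatory light chains to heavy chains), i.i.d. residues with
configurable composition (uniform by default), short activity-annotated
catalogues, motifs planted in cleavage-compatible flanking contexts, and
plate readouts whose noiseless values invert exactly to a known true
inhibition. Plate noise defaults to Gaussian with σ = 0.02 absorbance
units per well, a typical microplate-reader replicate spread; the ACE
simulation applies it to the two endpoint absorbances of each kinetic
well (initial absorbance 1.0, control drop 0.45 over a 30-minute read),
the DPP-IV simulation to all four endpoint wells (blank/negative 0.05,
positive 1.05).

Real proteins are not i.i.d. strings: they have repeats, domain
composition bias and homology structure, and real catalogues are curated,
redundant and version-dependent. Passing tests therefore demonstrate that
the *engine* is correct (rule evaluation, fragment bookkeeping, matching,
counting, formula inversion), not that any particular biological count is
right — absolute hit counts depend entirely on the catalogue snapshot
supplied. Randomness uses numpy's PCG64; each operation draws from its own
substream derived from the master seed via `SeedSequence(seed,
spawn_key=(k,))`, so adding an operation never perturbs another's draws.

Motif planting inserts the motif with a left flank drawn from the residues
the enzyme accepts at P1 before the motif's first residue, and requires
the motif's own C-terminal residue to be cleavable (with an admissible
right neighbour) — otherwise the motif could never be released intact and
planting raises an error, as it does for internally cleavable motifs. The
construction is verified by re-digesting; multi-copy planting re-checks
the released-instance count after each insertion so a later insertion
cannot silently destroy an earlier copy. When exact-count recovery is
asserted, background sequences are rejection-sampled to exclude chance
motif occurrences.

## Problem sizes and tolerances

Randomized equivalence checks run at 200 protein/catalogue pairs
(sequences ≤ 300, catalogues ≤ 50 entries) for profiling, 60 sequences ×
6 enzymes × 2 missed-cleavage settings for digestion, and 1000 random
proteins for the partition identity — sizes at which the brute-force
oracles are still exact and the whole suite runs in seconds. Statistical
recovery of a known inhibition uses 1000 replicates and a three-standard-
error band. Printed-value checks use ±0.01 Da for masses (last-digit
rounding) and ±0.05 for IER (the printed peptide contents are themselves
2-decimal roundings).

## Known limitations

- No kinetic, partial or pH-dependent digestion; distinct named enzymes
  stand in for condition variants (hence `pepsin_ph_gt2`).
- No fuzzy or homology matching; catalogue lookup is exact.
- No activity prediction from sequence features, no IC50 modelling, no
  MS/MS fragment-ion annotation or probabilistic identification scoring.
- The bundled catalogue is a demo fixture; scientific conclusions require
  a user-supplied catalogue, and cross-study count comparisons require the
  same catalogue version on both sides.
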