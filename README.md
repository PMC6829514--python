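# peptikit

In-silico proteolysis, bioactive-peptide profiling, and hydrolysate assay
arithmetic for food-protein peptide discovery.

## The problem

Food proteins (muscle proteins of fish and shellfish, milk caseins, plant
storage proteins, ...) encrypt short peptides that, once released by
enzymatic hydrolysis, inhibit disease-relevant proteases — most prominently
angiotensin-I converting enzyme (ACE, blood-pressure regulation) and
dipeptidyl peptidase IV (DPP-IV, incretin degradation and glycemic
control). Screening enzymes and substrates in the wet lab is slow, so the
standard first pass is computational: simulate complete digestion of known
protein sequences under each protease's cleavage specificity, match the
released fragments against a catalogue of experimentally characterised
bioactive peptides, and rank the enzymes by theoretical bioactive yield.
`peptikit` implements that screen as a reproducible local computation,
together with the peptide-mass verification used in proteomics protein
identification and the plate-assay arithmetic used to confirm activity in
vitro.

## The model

**Cleavage rules.** Specificity is declared over Schechter–Berger
positions. A rule fires at the bond between residues *i* and *i*+1 iff

```
(P1 ∈ p1_allow  ∨  P2 ∈ p2_allow)        (trigger)
∧ P1 ∉ p1_block                           (P1 veto)
∧ (p1prime_allow = ∅ ∨ P1′ ∈ p1prime_allow)
∧ P1′ ∉ p1prime_block                     (P1′ veto, e.g. proline)
```

where P1/P1′ flank the scissile bond and P2 precedes P1. An enzyme cleaves
where any of its rules fires; complete digestion cuts every fireable bond,
so zero-missed fragments partition the parent. Bounded missed cleavages
(as in MS database searches) and sequential multi-enzyme digestion (Lys-C
followed by trypsin) are supported. Six proteases ship by default
(pepsin pH > 2, stem bromelain, papain, trypsin, chymotrypsin A, Lys-C),
versioned as a rule set that is stamped into every report and overridable
by YAML config.

**Profiling.** The *activity profile* of a protein counts every catalogue
peptide occurrence as a substring (overlaps and repeats each count once) —
the classic "profile of potential biological activity". The *active
fragments* of a digest are released peptides whose **whole sequence** is a
catalogue entry; a bioactive dipeptide buried inside a longer released
fragment is not a hit. Matching is exact and direction-sensitive: AE
(a DPP-IV inhibitor) and its reversal EA (an ACE inhibitor) are distinct
entries.

**Assay arithmetic.** Degree of hydrolysis from OPA free-amino-group
measurements, DH% = (NH₂,tx − NH₂,t0)/(NH₂,total − NH₂,t0) × 100; ACE
inhibition from FAPGG kinetic slopes, (ΔA/min꜀ − ΔA/minₛ)/ΔA/min꜀ × 100;
DPP-IV inhibition from p-nitroanilide endpoints,
[1 − (Aₛ − A_b)/(A_pc − A_nc)] × 100; inhibition efficiency ratio
IER = inhibition% / peptide content (mg/mL); and linear Gly-Gly-Gly
standard-curve quantification.

## Worked example

Generate five synthetic proteins, rank three food-grade proteases against
the bundled demo catalogue, and verify a tryptic peptide's mass:

```bash
python -c "from peptikit import *; \
           write_fasta(random_proteins(SyntheticSpec(seed=1)), 'demo.fa')"
peptikit rank-enzymes --fasta demo.fa \
    --enzymes pepsin_ph_gt2,bromelain_stem,papain,trypsin --out rank.tsv
cat rank.tsv
```

```
enzyme          ACE inhibitor  DPP-IV inhibitor  other activities  total  counting
pepsin_ph_gt2   40             3                 2                 45     instances
bromelain_stem  11             5                 8                 24     instances
papain          1              0                 10                11     instances
trypsin         0              0                 10                10     instances
```

Pepsin tops the table because many catalogued ACE-inhibitory dipeptides
end in the bulky hydrophobic residues (F, W, Y, L) that pepsin accepts at
P1, so its cuts release them with an intact C-terminus. Each output comes
with a `.manifest.json` recording the tool and rule-set versions, input
checksums, and parameters.

```bash
peptikit mass --peptide IDSLEGSVSR --charges 2,3
```

```
peptide	IDSLEGSVSR
monoisotopic_mass	1061.53530
average_mass	1062.1448
m/z (2+)	531.77493
m/z (3+)	354.85238
```

The 2+ m/z of 531.77 is what a doubly charged signal for this peptide
reads in an orbitrap survey scan (adjacent isotope signals 0.5 Th apart).
Assay tables work the same way: `peptikit assay ier --in readouts.tsv
--out ier.tsv` appends an `ier` column, e.g. 60.32% inhibition at
2.42 mg/mL peptide content gives 24.93 %/(mg/mL).

The bundled catalogue (`peptikit/data/catalogue_demo.tsv`, 127 entries) is
a synthetic demo fixture of literature-typical di-/tripeptides — not a
copy of any hosted database — so absolute counts against it are only
meaningful for comparing enzymes within one run. Real screens should load
a user-supplied catalogue (`--catalogue db.tsv`).

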