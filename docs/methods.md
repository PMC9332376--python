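# Methods

## Scope and data model

`mitocompare` analyses *annotated* circular mitochondrial genomes. The unit
of input is a `MitoAnnotation`: a genome length, an ordered list of gene
features (13 protein-coding genes, 22 tRNAs, 2 rRNAs, one control region),
and optionally the nucleotide sequence. Coordinates are 1-based and
inclusive on both ends (the GenBank convention); a feature whose end is
smaller than its start wraps the sequence origin. Strands are H
(heavy/majority — the strand the sequence is written on) and L
(light/minority). Everything downstream — codon usage, junction
accounting, gene order, control-region structure — is a deterministic
function of this object, so coordinate-only inputs (published feature
tables without sequence) are first-class: sequence-dependent steps are
skipped with a warning rather than failing.

Gene names are normalised through a controlled vocabulary
(`nad1..6/nad4l, cox1..3, atp6/atp8, cob`, one-letter tRNA tokens, `rrnL`,
`rrnS`, `CR`). The Leu/Ser isoacceptor labels follow the anticodon
whenever one is given: L1 = UAA, L2 = UAG, S1 = UCU, S2 = UGA. Some
nomenclatures invert the Leu numbering; the anticodon field is treated as
authoritative and a bare "tRNA-Leu" without an anticodon resolves to an
explicitly ambiguous token.

## Genetic code and codon usage

The default code is NCBI translation table 5 (invertebrate mitochondrial:
UGA→Trp, AGA/AGG→Ser, AUA→Met), taken from Biopython's codon tables and
cross-checked in the test suite against an independently hand-typed
64-entry table. Start codons default to the ATN set {ATG, ATA, ATT, ATC};
stops are {TAA, TAG}. Codons containing N translate to X and never match
a start or stop.

Relative synonymous codon usage of codon *c* in family *f* is

    RSCU(c) = n_c / (N_f / k_f)

with *N_f* the family total and *k_f* the family size. Families are the
synonymous classes induced by the code in use — under table 5, serine is
a single eight-codon family (UCN + AGN) and tryptophan is {UGA, UGG}.
Two deliberate conventions:

* **Stop codons are counted** in the usage table and form their own
  two-codon family. A genome whose 13 PCGs all end in TAA therefore shows
  n(UAA) = 13 with RSCU(UAA) = 2, which is how published mitogenome codon
  tables read.
* **Incomplete terminal codons** (a trailing TA or T, completed to UAA by
  transcript polyadenylation) are excluded from codon counts — there is
  no defensible amino-acid assignment — but are reported in the start/stop
  classification as incomplete stops.

An empty synonymous family yields RSCU 0 for its codons and the family is
flagged rather than producing 0/0. Report output rounds half-up to two
decimals, the precision of published tables; internal computation is
full-precision.

## Junction accounting on the circle

For features sorted by start, the intergenic nucleotide count of a
junction is IGN = start(next) − end(prev) − 1; negative values are
overlaps. The wrap junction through the origin is always included, so the
conservation law Σ lengths + Σ signed IGN = genome length holds on every
fully annotated circle and is enforced as a property test. IGN is
strand-independent by construction.

Published tables often print their own IGN column. It is parsed into
`stated_ign` and treated as a claim: junction analysis always recomputes
IGN from coordinates and emits a discrepancy list for rows where the two
disagree. For the bundled *Tapinoma ibericum* table this list contains
exactly two rows (tRNA-Tyr: printed 56 vs computed 33; tRNA-Asp: printed
69 vs computed 0) — the printed table is internally inconsistent there,
and the package deliberately adopts neither value silently.

The nad4l/nad4 audit reports whether the ancestral 7-bp overlap (the
conserved ATGATAA window, tied to bicistronic expression of the pair) is
present or replaced by a spacer, and classifies the spacer by simple
composition rules: a "TA run" when ≥ 80% of it is consecutive TA
dinucleotide repeats, a "G run" when ≥ 80% G, "A+T-rich" at A+T ≥ 0.8,
otherwise "mixed". The 80% thresholds are package policy — the source
descriptions are qualitative — and are configurable.

## Gene order and rearrangements

A genome's order is a circular signed permutation over the 37 genes plus
CR, rotated to start at CR; equality is rotation-equality (reflections
are distinct, since strands fix reading direction). The ancestral
pancrustacean–insect arrangement is a package constant; its
minority-strand assignments follow the standard insect arrangement.

Cluster calls read the observed order of {I,Q,M} between CR and nad2 and
of {W,C,Y} between nad2 and cox1, ignoring strand (as the field's
MIQ/WYC labels do); cluster genes found outside their region are reported
as translocations with their observed neighbours.

The breakpoint distance between two orders is the number of signed
adjacencies (unordered neighbour pairs with relative orientation,
canonicalised so both traversal directions agree) of one order missing
from the other, after restricting both to the shared gene set. It is a
pseudometric and is zero iff the orders are rotation-equal. Event
inference is deliberately minimal: any single gene whose removal makes
the two orders rotation-equal explains the difference as a one-gene
event; ties (e.g. C vs Y for a WCY↔WYC shift) are broken by reporting the
lexicographically smallest gene with the alternatives noted, and anything
not explainable by one gene is returned as an unresolved adjacency
listing. No sorting-by-reversals/DCJ machinery is attempted — observed
ant rearrangements in this region are single-tRNA events.

## Control region

The control-region span comes from the annotation when present, otherwise
from the largest unannotated gap on the circle. Two structure finders
operate on the region sequence:

* **Tandem repeats.** Exhaustive (start, period) scan for maximal runs
  with ≥ `min_copies` copies (fractional final copies reported). Defaults
  `min_period=8`, `min_copies=2.0`: reported repeat periods in these ants
  are 11–33 bp, and 8/2.0 captures all of them while suppressing trivial
  AT-dinucleotide structure. Overlapping reports of one array at harmonic
  periods are merged to the *shortest* (primitive) period: the primitive
  period is the canonical description, and merging to longer harmonics
  would misreport a 13-bp × 5 array as 26-bp × 2.5. Every report is
  re-verified literally against the sequence by an independent checker.
* **Stem-loops.** All maximal perfect inverted repeats: for every loop
  window inside `loop_range` the arms are extended outward while they
  remain exact reverse complements; hairpins whose arms are contained in
  a larger reported hairpin are dropped. "Perfect" means zero mismatches,
  per the source observations; no thermodynamic model is used, and a
  mismatch-tolerant mode is out of scope. Defaults `min_stem=8`,
  `loop_range=(3, 15)`: observed spans of 27–30 bp imply stems around
  11–12 with short loops. Note that maximality is taken seriously: in a
  hairpin like GGGGG-AAATTT-CCCCC the A/T bases flanking the loop also
  pair, so the maximal stem is 6 with a 4-nt loop, not the visually
  obvious 5/6. Ranking is stem length desc, loop length asc, position.

Both finders are case-insensitive and are tested for set-equivalence
against brute-force enumerations (O(n²)–O(n³), fine at control-region
scale of a few hundred bp).

## Synthetic mitogenomes

The generator realizes a `SimSpec` into a sequence-bearing annotation
plus a `SyntheticTruth` of everything planted. Defaults reproduce the
study genome's conditions: MIQ+WYC arrangement, genome-wide A+T target
0.848, codon profile taken from the bundled 3695-codon usage table, the
−3 (I/Q) and −7 (atp8/atp6, via the conserved ATGATAA window) overlaps, a
104-bp spacer before nad2, a 5-bp nad4/nad4l spacer, and a 341-bp control
region carrying a 12+5 hairpin (span 29, inside the observed 27–30
window) and no tandem repeat.

Choices that matter:

* **Codon sampling** is i.i.d. from the profile with stops excluded,
  start codons drawn from the ATN set and the stop appended; no codon
  autocorrelation or amino-acid-level constraint is modelled. This is
  sufficient for RSCU/percent recovery tests, not for realistic protein
  evolution.
* **Composition is per class.** The codon profile pins coding A+T at
  ~0.816, so a single filler composition could not reach a genome-wide
  0.848. rRNAs are filled at A+T 0.885 and the control region at 0.99
  (both as observed in these genomes), and the tRNA/spacer filler
  composition is solved so the genome-wide expectation hits the target;
  the realized value lands within a point on ≥ 10 kb genomes.
* **Overlap engineering.** The atp8/atp6 and (optionally) nad4l/nad4
  overlaps place the ATGATAA window across both reading frames; the
  window starts mid-codon on the upstream side, so the two bases before
  it are pinned to keep the straddling codon ATA and avoid creating a
  premature stop.
* **Planted CR features are guarded**: repeat motifs are drawn primitive
  (no shorter internal period), flanking bases are mutated to break
  tandem extension, hairpin loops end in non-pairing bases and flanks are
  set non-complementary, so the finders recover the planted coordinates
  exactly.
* The control region abuts its flanking genes unless a junction override
  says otherwise, matching how control regions are actually annotated
  (every base between the flanks).

What the generator does **not** emulate: substitution processes along a
tree, indels, codon autocorrelation, tRNA secondary structure, or
realistic rRNA models. A passing closure test therefore shows that the
analysis stages invert the generator's (explicit, simple) data model — it
does not validate annotation transfer on real, messy genomes.

Because the background is AT-rich, chance tandem repeats or short
hairpins can occur beside the planted ones; closure tests assert that the
planted feature is recovered exactly (coordinates, period/stem, copies),
not that it is the only report.

## Determinism and sizes

All randomness flows from one `numpy` `default_rng(seed)`; identical
specs produce byte-identical genomes, and reports are byte-identical
across re-runs. Default synthetic genomes are ~15.3 kb (the real genome
is 15,715 bp); codon-recovery checks pool two genomes (~7,400 codons),
where the 2-percentage-point tolerance on a 13% codon frequency is ≈ 5
binomial standard deviations. Brute-force oracles run on ≤ 400 bp regions
and ≤ 12-element toy permutations.

## Known limitations

* GenBank output encodes start/stop codons and anticodons in feature
  notes (so round trips are lossless); other tools will read the
  coordinates and gene names but may ignore those notes.
* Wrapped (origin-crossing) features are parsed and measured correctly,
  but the junction walk assumes at most the canonical wrap junction;
  pathological annotations with multiple origin-crossing features are not
  supported.
* Event inference stops at single-gene explanations by design; a genome
  two or more rearrangements away from the reference yields an
  "unresolved" adjacency report rather than a guessed scenario.
* The repeat finder reports arrays, not a minimal covering set: two
  planted arrays separated by less than one period can merge.
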