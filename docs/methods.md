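# Methods

`ophiopsin` re-implements, as a desk-scale reusable pipeline, the standard
workflow for cataloguing the opsin gene repertoire of a non-model echinoderm
from a draft genome assembly and an arm transcriptome, and for testing the
animal's wavelength-dependent photo-behaviour. This note records the models,
the parameters that matter, the numerical choices, and the limits of what
the synthetic-data tests demonstrate.

## The diagnostic model

Opsins are class-A GPCRs whose identity can be read off a handful of
residues once a candidate is expressed in the coordinate frame of a
reference rhodopsin. All positions in this package use 1-based numbering on
a 348-residue rhodopsin anchor:

| site | position(s) | canonical state | meaning |
|---|---|---|---|
| Schiff base | K296 | lysine | covalent retinal attachment; *bona fide* opsin marker |
| counterion (vertebrate) | 113 | E (Y in most invertebrates) | stabilises the protonated Schiff base |
| counterion (ancestral) | E181 | glutamate | ancestral counterion position |
| DRY-like | 134–136 | [DE]-R-[YFWCSH] | G-protein activation switch |
| NPxxY(x)6F | 302–313 | N,P,x,x,Y + 6x + F | C-terminal helix coupling pattern |
| triad | 310–312 | NxQ ciliary / HxK rhabdomeric / HxS derived | lineage-diagnostic triad inside the pattern |
| disulfide | C110/C187 | cysteines | structural disulfide |
| palmitoylation | C322/C323 | cysteines | membrane anchor |

Position equivalence is established by **one global alignment per candidate
against the anchor** (BLOSUM62, gap open 10, gap extend 0.5, end gaps
penalised). A pairwise map is deterministic and testable, unlike a
progressive multiple alignment whose columns shift with the input set; the
cost is that two candidates are never constrained to agree with each other,
only with the anchor. Sites outside a fragment's aligned coverage are
reported `not_covered`, never guessed; a candidate is *bona fide* iff the
mapped 296-equivalent is lysine, `false` iff that site is covered by another
residue, and `indeterminate` otherwise.

The NPxxY(x)6F call constrains only the mapped N302, P303, Y306 and F313;
internal x positions are free and insertions between mapped sites do not
break the call (the residue map, not a sliding window, decides).

### The anchor fixture

The shipped anchor (`Rn-rhodopsin`) is the canonical 348-residue rhodopsin
frame reconstructed for this package: it carries every diagnostic residue at
its canonical position and a realistic seven-helix hydropathy profile, and
`validate_scheme` re-verifies all sites at load time. The nine `Sp-opsin`
panel entries and the melatonin-receptor-like outgroup are **synthetic
exemplars** (seeded derivations from the anchor with family-specific
divergence, triad class, counterion state, and — for the peropsin exemplar —
a Schiff-base knockout, mirroring the pseudo-opsin case). They provide the
similarity structure and motif states the classifier needs; they are not the
real sea-urchin protein sequences, so absolute similarity percentages
against this panel are not comparable with published similarity tables —
only the ranking behaviour is meaningful. `scripts/make_reference_fixtures.py`
regenerates the fixtures byte-identically.

## Mining

Translated search is exhaustive Smith–Waterman of all six reading frames of
every contig against every panel protein (no heuristic seeding by default; a
4-mer co-occurrence prefilter can be switched on and is verified equivalent
on the test fixtures). Three numerical choices matter:

* **Hit trimming.** With gap extension at 0.5, a local alignment gladly
  bridges a 30-residue gap for ~25 points, gluing chance matches onto a true
  hit and corrupting its reference span. Every hit is therefore end-trimmed:
  alignment blocks delimited by gap runs of ≥4 columns are dropped from the
  ends while below 50% identity, then single columns are trimmed while the
  outermost 20 columns stay below 50% identity. True homology at the
  divergences this pipeline targets (≤30%) sits near 70–80% identity and is
  untouched.
* **Score cut-off, default 120** (matrix units, on the trimmed alignment).
  Measured on random 500-residue frames against the panel, raw local scores
  average ≈52 under these gap penalties and trimmed scores reach at most
  ≈78 in 1 650 trials, so 120 leaves no measurable false-positive rate while
  true fragments score ≥400. The cut-off is declared, not inferred from any
  published search parameters, and is configurable.
* **Merge tolerance, 20 residues.** Fragments matching the same reference
  merge into one gene when their reference spans are disjoint; up to 20
  residues of overlap are forgiven because trimmed alignment ends still
  jitter by a few positions. True paralogs overlap over most of their
  length, and the rule keeps a 51-residue overlap separate.

Candidates are validated by reciprocal best hit: the merged protein is
searched back against the panel plus a decoy database (non-opsin GPCRs); the
candidate survives only if the top reverse hit is an opsin. Transmembrane
architecture is recorded with a Kyte–Doolittle sliding window (window 9,
threshold 0.7, minimum run 8 — calibrated once so the anchor yields exactly
its seven helices, then frozen) but never gates: incomplete fragments are
expected and are kept flagged.

Exon structure is not modelled. A multi-exon or split gene surfaces as
several disjoint fragments and is handled by the merge rule; spliced
alignment is out of scope.

## Classification and placement

Family assignment rests on three lines of evidence: (1) family of the
highest-similarity reference on the **trimmed local alignment** (similarity
= columns sharing a conservation group / all alignment columns, gaps in the
denominator; groups {GAST} {ILVM} {FYW} {KRH} {DENQ} {C} {P}); cells whose
alignment is shorter than 50 residues are excluded from the argmax because
percentages at tiny lengths are meaningless; (2) the triad class (NxQ
supports ciliary, HxK rhabdomeric, anything else is neutral); (3) the family
of the nearest reference tip on the tree. Confidence is `consistent` only
when all available evidence agrees. Names follow the reference numbering:
the base number of the best reference, `.1/.2/…` suffixes for multiple genes
sharing a base (ordered by descending similarity), `.A/.B` letters for the
disjoint fragments of one merged gene.

Tree placement is a deliberate stand-in for full likelihood/Bayesian
inference (out of scope): sequences are truncated to the conserved 7-TM core
(residues 68–357 of the `Sp-opsin 1` truncation anchor, 290 anchor columns,
insertions inside the core retained), stacked into an anchor-indexed
pseudo-alignment (each residue placed at its mapped anchor column;
insertions relative to the anchor have no column and drop out), and joined
by neighbor joining on p-distances (1 − fractional identity; a Poisson
correction exists but is off by default). NJ ties are broken by joining the
pair with the lexicographically smallest representative leaves, so trees are
reproducible; NJ is exact on additive matrices, which the tests verify.
Support values are bootstrap proportions over 500 column resamples of the
pseudo-alignment. The tree corroborates family calls; it never overrides
the similarity evidence.

## Expression detection

Transcripts are translated in six frames and locally aligned against each
gene protein; a gene is **detected** when its best alignment has identity
strictly above 99.9% over at least 30 residues. At the short windows partial
transcripts produce, one mismatch in 33 residues is ~97%, so the rule
effectively demands a perfect protein-level match. The output column is
called `detected`, not "expressed": absence separates poorly between true
silence and sequencing depth, and the rule cannot tell them apart.

## Behaviour statistics

The design mirrors a five-aquarium day/night experiment: 18 animals per
treatment (white, green, blue, red, no-light control), two observations per
phase per day for 8 days, the response being the number of arms extended
into the water (at most two per animal, hence counts in [0, 36]). The unit
of replication defaults to the **daily mean** (observations within a day are
averaged; raw-observation mode is available) because within-day repeats are
not independent. Per treatment: an F test for variance homogeneity
(two-tailed, larger variance in the numerator), Shapiro–Wilk normality per
group (annotations only — they do not gate the verdict), and a
pooled-variance unpaired two-tailed t test at α = 0.05 (Welch available
behind a flag). No multiple-testing correction is applied across the five
treatments; with five tests this inflates the family-wise error and is
retained deliberately as the classical per-treatment analysis — a documented
limitation.

## The synthetic-data generator

The generator emulates exactly the statistical structure the analysis
assumes, with ground truth attached:

* **Genes** start from a family exemplar, receive i.i.d. substitutions at a
  stated divergence (default 0.25) outside the protected diagnostic
  positions, optional site knockouts (e.g. K296→R for a non-*bona fide*
  gene), uniform-codon back-translation, and optional splitting into two
  fragments with disjoint anchor spans (the split-gene scenario).
* **Assemblies** embed each fragment at a random offset and strand inside
  uniform random background (400 nt of flank by default), alongside decoy
  GPCR genes derived from the melatonin-receptor-like template (15%
  divergence) and pure background contigs. The default specification has 13
  genes across six families — one ciliary, six rhabdomeric paralogs, one Go,
  two basal-branch, one split RGR gene, two neuropsins — with three genes
  expressed, two decoys, and three background contigs.
* **Transcripts** are exact CDS copies of the expressed genes with an
  optional per-base substitution rate.
* **Behaviour tables** draw night counts from Binomial(36, 0.5) and day
  counts from Binomial(36, 0.5·(1−effect)); default day-suppression effects
  are 0.5 for white/green/blue and 0 for red and the control, encoding the
  suppressed-by-short-wavelengths / unaffected-by-red-and-dark pattern. A
  weak red effect (e.g. 0.15) reproduces the marginal-verdict regime and is
  exercised in the tests as an explicit scenario.

Everything is a pure function of the seed; identical seeds give
byte-identical files.

**What passing synthetic tests do not show.** Real assemblies have introns
(the generator embeds contiguous CDS; real multi-exon genes would fragment
further and rely more heavily on the merge rule), biased codon usage,
repetitive background rather than uniform random nucleotides, and reference
panels whose families are unevenly diverged. Real behavioural counts are
overdispersed relative to a binomial and serially correlated across days.
The synthetic results demonstrate correctness of the machinery under the
stated model, not field performance.

## Degenerate inputs and tie-breaks

Empty sequences, stray alphabet characters and stop/unknown residues in
molecular-weight input raise input errors naming the offending symbol.
Sequences shorter than the hydropathy window warn and return no helices.
Local alignments with no positive-scoring pair are empty with score 0, and
identity/similarity is undefined (error) on an empty alignment. Zero
variance in one behaviour group makes the F statistic infinite (flagged);
zero variance in both is an error; constant groups make Shapiro–Wilk
undefined (NaN, flagged). Co-optimal alignment tracebacks resolve to the
aligner's first enumeration, which is deterministic for fixed inputs.

## Problem sizes

The shipped evaluation (`scripts/acceptance.py`) scores family recovery and
decoy admission over 40 seeded end-to-end assemblies, the expression rule
over 50 seeds, the t-test null calibration over 2 000 simulated tables, and
the verdict pattern over 60 seeds; the test suite runs the same checks at
up to 100 seeds. These sizes give binomial standard errors comfortably
inside the asserted margins while keeping a full run in minutes on one CPU.

## Known limitations

* Family calls lean on a synthetic reference panel; swapping in a real panel
  (FASTA + sidecar TSV) is supported and changes only the fixtures.
* Families represented by a single panel exemplar cannot be validated by
  leave-one-out classification (removing the only exemplar removes the
  class); the leave-one-out test covers the multi-member families.
* The NJ stand-in ignores rate heterogeneity and alignment uncertainty;
  supports on deep splits should be read qualitatively.
* The expression rule is presence/absence at one threshold; no abundance
  model.
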