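# Methods

`tubemir` re-implements, as a tested library, the analysis chain of a
single-end small-RNA sequencing study of a non-model invertebrate tissue
(the tube foot of the sea cucumber *Apostichopus japonicus* is the motivating
system): read filtering, priority annotation against mature-miRNA and ncRNA
references, nucleotide-composition statistics, hairpin-based novel-miRNA
screening, cross-tissue specificity calling, dual-criterion target
prediction, and 2^-ΔΔCt qRT-PCR analysis. Because the original raw data are
not required, every stage is exercised against a synthetic experiment with
per-read ground truth.

## Read filtering

Each raw read is assigned exactly one category, tested in a fixed order
(low quality → 5′ adapter contaminant → 3′ adapter null / insert null →
poly-nucleotide → excess N → low complexity → length outside 18–40 nt →
clean), so the categories always partition the library and the report is
independent of read order. Thresholds, all config-exposed with these
defaults:

- low quality: mean Phred < 20 or more than 4 bases with Phred < 10;
- adapters located by exact match of their first 8 bases, leftmost
  occurrence wins (a ≤1-mismatch scan is available but off by default, to
  keep classification deterministic);
- poly-nucleotide: one base ≥ 90% of the insert;
- excess N: N fraction > 10%;
- low complexity: overlapping-dinucleotide Shannon entropy < 1.0 bits. This
  is a deliberate, simple stand-in for a repeat masker; it catches mono- and
  dinucleotide repeats but not longer repeat units.

Clean inserts are collapsed to unique sequences with copy counts;
percentages are formatted with half-up rounding, which reproduces printed
summary tables exactly.

## Annotation

Conserved-miRNA matching is full-length exact equality after T/U
normalisation — the strictest reading of a perfect-match rule; there is no
isomiR tolerance by default. Classes are resolved in the priority order
miRNA > rRNA > tRNA > snRNA > snoRNA; everything unmatched feeds the
novel-miRNA screen. A read matching k mature miRNAs adds 1/k of its copies
to each name ("fractional", keeping per-class totals conserved); "first
name wins" is available as an option.

## RNA folding

Structure prediction is a Zuker-style dynamic program over a simple
stacking model rather than the Turner nearest-neighbour parameter set:

- admissible pairs: Watson–Crick plus G:U, hairpin loops ≥ 3 nt;
- a stack of two adjacent pairs contributes −(0.5·(s₁+s₂)+0.5) kcal/mol
  with pair strengths G:C = 3, A:U = 2, G:U = 1 (so stacks range from −1.5
  to −3.5 kcal/mol);
- hairpin loops cost 4.5 + 0.3·(size−3), bulge/interior loops
  2.0 + 0.4·unpaired (capped at 30 unpaired), multibranch loops
  4.0 + 1.0·branch + 0.2·unpaired;
- the empty structure scores 0, so reported MFE ≤ 0 always.

`energy_of_structure` is the definition of this model; the dynamic program
returns its exact optimum, verified against exhaustive enumeration of all
admissible structures for sequences up to 18 nt. Positions can be
constrained unpaired, which is how target-site accessibility is computed.
Absolute energies are not comparable to Turner-model values; the engine is
used for hairpin detection and relative stability, where only ordering and
a calibrated threshold matter.

## Novel-miRNA screen

Unannotated reads are mapped to scaffolds by exact substring match,
overlapping hits are clustered, and two ~70-nt windows are excised per
cluster (mature arm assumed 5′ or 3′). A window is accepted when

1. the fold is a single stem-loop around the mature read (exactly one
   terminal loop inside the outermost base pair touching the mature arm);
2. the mature arm is anchored near both ends (≤ 6 nt unanchored in total, a
   proxy for the 2-nt 3′-overhang duplex geometry left by Dicer) and pairs
   with a contiguous, disjoint star region;
3. the trimmed precursor refolds with MFE ≤ −18 kcal/mol and ≤ −0.2 kcal/mol
   per nucleotide, with ≥ 60% of the mature arm paired.

The −18 kcal/mol threshold is calibrated to this package's energy model (a
20-pair stem scores roughly −50). The support score,
log₁₀(reads) − MFE/10 + paired-fraction, is a monotone ranking heuristic
and explicitly **not** a miRDeep2 probability; published miRDeep2 scores are
not reproducible from it.

A dinucleotide-shuffle control is part of the test suite. Its measured
rejection rate is ~80%, not arbitrarily high, and deliberately so: a shuffle
of a precursor's composition (a mature arm plus its near-complement)
frequently re-forms a genuine stem-loop, which the detector then correctly
accepts. The residual acceptances are a property of the control, not
detector errors.

## Cross-tissue specificity

Counts are normalised per tissue to the total reads of identified miRNAs
(not to all clean reads). The fold change between the focus tissue and a
comparison tissue is the ratio of proportions with a signed-reciprocal
convention (r < 1 reported as −1/r, so two-fold depletion reads −2); a
pseudo-proportion of 0.5 reads (scaled by the library whose term is zero)
handles absent miRNAs. A miRNA is tissue-specific only when the same
direction exceeds ±2 against **every** comparison tissue. No p-value is
attached: the rule is a pure threshold, with qPCR as the validation arm.

## Target prediction

Two re-implemented scorers are intersected:

- **Method A** (alignment + energy): local antiparallel complementarity
  alignment scoring +5 per Watson–Crick pair, +1 per G:U, −3 per mismatch,
  affine gaps (−8 open, −2 extend), columns on miRNA seed positions 2–8
  doubled; acceptance needs S ≥ 140, duplex ΔG ≤ −17 kcal/mol, and a strict
  seed (no G:U, no gaps). A perfect 22-nt duplex scores 5·22 + 5·7 = 145,
  so the S ≥ 140 default implies near-full-length complementarity.
- **Method B** (seed + accessibility): a seed match (G:U tolerated) plus
  ΔΔG = ΔG_duplex − ΔG_open ≤ −10 kcal/mol, where ΔG_open = MFE(local
  window) − MFE(window with the site held unpaired) ≤ 0, computed with the
  folding engine over a 50-nt window. Burying a site in structure makes
  ΔG_open more negative and ΔΔG larger. The −10 kcal/mol cutoff is this
  package's choice: accessibility methods are conventionally rank-based,
  but an intersection rule needs a threshold.

Duplex energies use the same stacking table as the folder with a
1.5 + 0.4·unpaired loop penalty. Both the aligner and the duplex-energy
program are verified against independent exhaustive oracles (a quartic
column DP with explicit gap runs; depth-first enumeration of all monotone
complementary pairings). A transcript is a potential target only when a
method-A site and a method-B site overlap by ≥ 1 nt on it. Scanning is
restricted to annotated UTR intervals when provided.

## qPCR analysis

ΔCt = Ct_target − Ct_reference per replicate and tissue; ΔΔCt subtracts the
calibrator tissue's mean ΔCt (default calibrator: tube foot, config-
exposed); relative expression is 2^−ΔΔCt. Folds are computed per replicate
and then averaged, so replicate variance propagates into the reported sd.
Tissues are grouped by pairwise Welch t-tests on replicate ΔCt values at
α = 0.05, rendered as a compact letter display via the standard
insert-absorb algorithm.

## Synthetic experiment

The generator emulates the study conditions: mature miRNAs 18–25 nt with
the mode at 22 nt (63% of the length mass) and a 60% uracil bias at
position 1; a library mix dominated by adapter-only products (30%) and
miRNA reads (45%) with small ncRNA, low-quality, poly-nucleotide and
high-N fractions; miRNA abundances rank-skewed as 1/(rank+25) (the offset
floors the rarest miRNA at a usable read count); four tissue-specific
miRNAs planted at 8× in the focus tissue among the low-abundance ranks, so
renormalisation distorts the remaining proportions by well under the
2-fold calling threshold; scaffolds with planted precursors (mature + 8–20
nt loop + star with 1–4 interior mismatches + 2-nt overhang); transcripts
with perfect-complement target sites flanked by low-pairing A/C runs; and
Ct tables with reference genes that are exactly proportional across
tissues and Gaussian noise on target Ct only.

Every planted feature is validated against its detector at generation time
and regenerated until it passes, so ground truth and detector semantics
agree by construction. Reads are likewise verified against the filter
cascade, which is what makes exact truth-table agreement a meaningful
invariant rather than a statistical one.

What the generator does **not** emulate: sequencing errors inside inserts,
quality-score correlation along the read, isomiR heterogeneity,
multi-locus gene families, expression dispersion between biological
replicates (the fold-change rule, like the original design, has none), and
real secondary-structure statistics of genomic background. Passing tests
therefore demonstrate correctness of the implementations under the stated
model, not performance on real libraries.

## Problem sizes and determinism

The shipped validation uses desk-scale sizes chosen to make every
statistical margin wide: three tissues × 50,000 reads × 100 miRNAs for
specificity recovery; 20 libraries × 3,000 reads for cascade conservation;
6 planted hairpins; 30 planted target sites over 20 transcripts with a
shuffled-decoy control; 200 noisy Ct tables; 500-sequence/pair oracle
sweeps (folding up to 18 nt, alignment windows up to 12 nt, duplexes up to
10 nt). All randomness flows through seeded NumPy generators; identical
(config, seed) gives byte-identical FASTQ/TSV outputs, which the run
manifest records as SHA-256 checksums.

## Known limitations

- The energy model is intentionally minimal; absolute MFE values and the
  −18/−17/−10 kcal/mol thresholds are calibrated within this model only.
- Exact-match annotation misses isomiRs and any sequencing error in a
  miRNA read (such reads fall into "others").
- The novel-miRNA score ranks candidates sensibly but has no probabilistic
  interpretation.
- Accessibility uses a single local window (50 nt default) rather than an
  ensemble average over window placements.
- qPCR analysis assumes perfect amplification efficiency (no
  efficiency-corrected model).
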