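# Methods

## The biological model

V(D)J recombination is initiated by the RAG1/RAG2 complex at recombination
signal sequences (RSSs): a conserved heptamer (consensus `CACAGTG`) and
nonamer (consensus `ACAAAAACC`) separated by a poorly conserved spacer of
12±1 bp (12-RSS) or 23±1 bp (23-RSS).  RAG cleaves at the heptamer/coding
border and recombines only pairs with unlike spacer classes (the 12/23
rule).  Near-consensus *cryptic* RSSs outside the antigen-receptor loci
can be cleaved too; when a 23-RSS and a 12-RSS face each other across a
chromosomal segment — both nonamers pointing into it — recombination
excises the segment and NHEJ seals a coding joint into which terminal
deoxynucleotidyl transferase (TdT) adds random non-templated nucleotides.

The package models the archetypal case: a tumour-suppressor gene whose
last exon carries a cryptic 23-RSS "hotspot" and whose downstream region
carries eight cryptic 12-class sites at 101–557 kb, producing eight
recurrent deletion types that arise independently in multiple leukemic
subclones.  Bulk copy-number assays (MLPA, SNP arrays) see only clones
above a substantial cell fraction; breakpoint-spanning PCR sees far
smaller subclones, which is how purely subclonal deletions are found in
bulk-negative samples.

## RSS scanning and scoring

`scan` enumerates every (heptamer, spacer length, nonamer) window on both
strands — six spacer lengths per window position — and reports candidates
whose position-wise Hamming distances to the consensus elements fall
within thresholds.  Conventions and defaults:

* **Obligate CAC.**  The heptamer's first three bases must be `CAC` in
  reading orientation (overridable).  This is the canonical functional
  requirement for RAG cleavage, and every documented functional cryptic
  heptamer at this locus class conserves it.
* **Thresholds.**  `max_heptamer_mm = 3`, `max_nonamer_mm = 6`: the
  loosest documented functional motifs are a heptamer with 3 mismatches
  (all outside CAC) and a nonamer with 6 mismatches, so the defaults admit
  every documented site with zero margin.  Raising either threshold never
  removes candidates (monotonicity is property-tested).
* **Score** = 2·heptamer + 1·nonamer mismatches, lower is better; the
  heptamer is weighted double because cleavage occurs there.  Weights are
  arguments, not constants.
* **Coordinates** are 0-based half-open on the plus strand.  A
  minus-strand candidate's `heptamer_start` is the plus-strand offset of
  the 7-mer whose reverse complement is the heptamer; its cleavage edge
  (the heptamer/coding border) is therefore `heptamer_start + 7`, versus
  `heptamer_start` on the plus strand.
* **Pairing.**  `pair_rss` admits a pair iff spacer classes differ and the
  left RSS lies on the plus strand, the right on the minus strand — the
  deletion-forming geometry in which both heptamers flank the excised
  segment.  The predicted deletion runs between the two cleavage edges.

The scanner is validated against an independent naive enumerator on random
sequences (set equality of all candidate tuples) and against the embedded
ground truth of the synthetic locus.

## Junction decomposition

`decompose(junction, proximal_ref, distal_ref)` uses greedy maximal
matching: the proximal break is the longest common prefix of junction and
proximal reference, the distal flank the longest common suffix with the
distal reference, and the unexplained middle is the non-templated
insertion.  If the two maximal matches overlap, the overlap is reported as
microhomology with an empty insertion and the split placed at the
proximal-most consistent position (a fixed convention; the data motivating
the package showed insertions, and microhomology support is a defined
extension).  Each anchor must contain at least `min_anchor = 10` exact
bases — breakpoint-spanning PCR assays imply long exact anchors — else the
call gets status `unrelated` rather than an exception, since co-amplified
unrelated fragments are a real observation.

Note that when an insertion's first base equals the next proximal
reference base (or its last base the preceding distal base), the greedy
split and the generating split differ while reconstructing the same
junction; the decomposition is then inherently ambiguous and the greedy
convention is deterministic.  The generator can (and by default does)
produce non-extendable insertions, for which recovery is exact — the
parameter-recovery suite shows 100% over 10,000 events.

`cluster_breakpoints` is single-linkage with a 10 bp gap tolerance
(clusters in the motivating data are tens of kilobases apart, so the
tolerance is uncritical but fixed); clusters are labelled I, II, … in
genomic order with the median member as representative.
`hotspot_window(positions, fraction)` returns the minimal inclusive
interval containing ⌈fraction·n⌉ positions (leftmost on ties), verified
against an exhaustive interval search.  `classify_deletion` assigns the
nearest catalogue cluster within 50 bp, else `novel` — e.g. a breakpoint
2 kb downstream in a 3′UTR classifies as novel.

## Cohort statistics

Deletion prevalence per group uses a 2×2 table (group yes/no × deletion
+/−) tested with Pearson chi-square **without continuity correction**
(df = 1, two-sided); the uncorrected statistic is required to reproduce
the reference cohort's printed P-values from its counts.  When any
expected cell count is below 5 the automatic rule switches to Fisher's
exact test, two-sided by the minimum-likelihood method (the common
statistical-package default; a tail-doubling variant sits behind a flag).
Fisher's P equals brute-force hypergeometric enumeration for all tables
with total ≤ 200 (property-tested).  The automatic rule can be overridden
per table, and the packaged reference-count reproduction pins each row to
the test originally reported for it (chi-square everywhere, Fisher for the
17-sample MLL group).  P-values are unadjusted for multiple testing, as in
the original analysis; summaries round to 3 decimals, machine outputs keep
full precision.

Samples with a missing subgroup assignment are excluded per comparison,
which is why yes+no totals vary between rows.

## ChIP / qPCR quantification

Percent recovery = `dilution × 2^(Ct_input − Ct_ChIP) × 100`; fold change
= `2^−ΔΔCt` relative to a calibrator sample, normalised to a reference
gene.  Replicate Cts are averaged per (sample, target) before either
formula; no efficiency calibration or error propagation is attempted.
Values above 100% recovery are possible (enrichment artifacts) and are
logged, not clipped.  Lineage contrasts use the classical equal-variance
Student's t-test (df = nA+nB−2); Welch's form is available via
`equal_var=False`.  Two identical zero-variance groups return t = 0,
P = 1 by convention.  ΔΔCt is invariant under adding a constant to all
Cts of one gene across all samples, but **not** under shifting a single
sample's target Ct alone; the suite tests exactly that asymmetry.

## The synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs:

* **Locus.**  Plus-strand storage with the gene annotated on the minus
  strand; hotspot 23-RSS inside the 200 bp last exon; eight distal
  12-class sites at fixed distances {101, 152, 203, 268, 330, 412, 489,
  557} kb × `scale_factor` (endpoints documented; interior values are a
  fixed generator choice).  Distal motifs are the documented cryptic RSS
  sequences of the eight deletion types, embedded on the minus strand so
  that both nonamers face the deleted DNA; for the one type at which no
  RSS was documented, the site carries the optimal consensus (a synthetic
  stand-in).  The background is i.i.d. uniform ACGT, rejection-sampled
  until no spurious zero-mismatch RSS exists: exact-consensus truth stays
  unambiguous while near-consensus noise remains, exercising candidate
  ranking realistically.  A scale below ~0.0015 would make sites overlap
  and is rejected with the minimal feasible scale in the message.
* **Events.**  Deletion type drawn from the empirical type spectrum
  (III 49%, V 15%, VIII 17%, rest uniform; uniform choice available).
  Telomeric breakpoints scatter as a mixture: 75% uniform in a 10 bp core
  around the hotspot cleavage edge, the rest uniform in the surrounding
  33 bp window; centromeric breakpoints jitter ±4 bp.  Insertions are
  uniform 1–10 nt with random bases (the source data describe random
  single-nucleotide additions without a length distribution; length 0 is
  configurable), rejection-sampled to be non-extendable into either flank
  so the generating decomposition is unique.
* **Cohort.**  722 B-lineage samples split into six cytogenetic subgroups
  with the reference prevalences (hyperdiploid 160 @ 3.1%, ETV6-RUNX1
  142 @ 19.0%, BCR-ABL1 23 @ 26.1%, MLL 17 @ 0%, other 180 @ 7.2%,
  unknown 200 @ 7.0% — overall ≈ 9%), plus 109 T-lineage and 26 normal
  samples that never carry deletions.  A positive sample's major clone
  fraction is uniform on (0.35, 0.95); up to three extra independent
  subclonal deletions occur with probabilities (0.17, 0.07, 0.03), so a
  sample can carry four unique deletions and ~27% of positives are
  multiclonal.  Bulk-negative samples carry purely subclonal deletions
  with probability 0.18.  Subclonal fractions are a symmetric Dirichlet
  split (over the subclones plus a residual normal compartment) of a total
  subclonal mass drawn between 2× the PCR limit and 0.9× the bulk limit —
  bounding the mass keeps subclonal carriers genuinely below the bulk
  detection threshold, which is what "subclonal" means operationally in a
  bulk-negative screen.  Detection thresholds: MLPA 0.30, PCR 0.01 clonal
  fraction (invented but mechanistically ordered: a bulk ratio assay
  versus an amplification assay; both configurable).
* **Ct tables.**  True recovery/fold-change tables are inverted through
  the quantification formulas to produce Cts, then perturbed with Gaussian
  noise (default σ = 0.1 cycles).  At σ = 0 the quantification module
  recovers the truth to machine precision, closing the loop.

What the generator does **not** emulate: sequencing error, alignment
artifacts, GC/repeat structure of real genomic background, copy-number
noise in MLPA ratios, relapse dynamics beyond resampling, and real
GRCh37 coordinates.  Passing parameter-recovery tests therefore
demonstrates the correctness of the analysis logic under the stated
generative model, not robustness to raw-data artifacts.

## Determinism and problem sizes

Every stochastic stage derives its stream from one seed (`numpy`
`default_rng` seeded with `[seed, stage-hash]`), so identical configs give
byte-identical outputs.  Default test and reproduction runs use the locus
at `scale_factor = 0.01` (~6.6 kb), 10,000 events for junction recovery
and hotspot measurement, the full 857-sample cohort, and an 89-sample
bulk-negative screen — sizes chosen so a complete run takes seconds while
binomial 3σ bands remain tight enough to be informative.

## Known limitations

* The scanner scores by mismatch counts, not an information-content model
  of RSS functionality (e.g. RIC scores); ranking among near-consensus
  candidates is correspondingly coarse, and a spurious candidate can
  outrank a true functional site within an annotation window.
* `decompose` assumes the junction's ends are error-free copies of the
  flanks; it performs exact matching, not alignment, so a sequencing error
  inside an anchor shortens the anchor rather than being absorbed.
* The Fisher/chi-square switch uses the expected-count-below-5 rule; for
  tables where the original analysis chose differently, the per-table
  override is the supported path.
* Subgroup assignments in the simulator are disjoint, whereas real
  cytogenetic classifications overlap and have per-marker missingness;
  the "unknown" group stands in for all missing-data patterns.
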