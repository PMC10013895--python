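# Methods

## The computation

`svsoma` operates entirely at the callset level: its inputs are SV
calls (VCF records with type, breakpoints, length and read support),
never reads or alignments. This matches the situation where primary SV
calling has already been done by a long-read caller on tumor and
matched normal samples and the remaining questions are which calls are
somatic, how they recur across a cohort, what repeat content they
carry, and which genes their breakpoints disturb.

### Matching predicate

All cross-callset reasoning uses one symmetric predicate. Calls `a`
and `b` match iff every applicable criterion holds:

* same SV type; same chromosome (both chromosomes for translocations);
* breakpoint distance ≤ `max_dist` (default 1000 bp), where distance is
  `|pos_a − pos_b|` for insertions, the maximum over both junction ends
  for translocations, and `max(|pos_a − pos_b|, |end_a − end_b|)` for
  spanning types. Evaluating both ends is stricter than a single-end
  radius and follows common SV-merge semantics;
* for DEL/INV/DUP, reciprocal overlap ≥ `min_reciprocal_overlap`
  (default 0.40), computed against the *longer* span, which is
  equivalent to requiring the ratio in both directions ("reciprocal");
* for all sized types (insertions included; translocations carry no
  length), relative length difference < `max_len_diff_frac` (default
  0.20), strict because the criterion is "less than", whereas the
  support and overlap thresholds are inclusive ("at least").

### Somatic derivation

Tumor calls pass a depth-proportional support filter: support ≥
`depth_support_frac × mean_depth` of that sample (default 0.3; the
per-sample depth from the metadata table is used, not a cohort
average). A filtered tumor call is then subtracted as germline when it
matches any normal call with support ≥ `min_normal_support` (default
2). The asymmetry is deliberate: depth-filtering the normal would
lower its recall and let germline calls through as false somatic
calls. Subtraction is idempotent and its output is always a subset of
the depth-filtered tumor callset.

### Cohort merge and recurrence

Somatic callsets from all patients are merged by single-linkage
clustering: clusters are connected components of the pairwise match
graph (complete linkage is available for stricter behaviour). Each
cluster's representative is its best-supported member (ties broken by
coordinate), and recurrence counts distinct *patients*, so two
fragmented calls in one tumor count once. A sorted positional index
limits candidate pairs to those within `max_dist`, which is sufficient
because breakpoint distance is a necessary match condition.

### Repeat classification

Two deliberately compact detectors stand in for full genome-annotation
suites; they are this package's own detectors, with every threshold a
keyword argument:

* **Tandem repeats.** For each candidate period `p` (1–100, shortest
  first) the sequence is compared against itself at lag `p`; the
  longest window whose mismatch fraction is ≤ 0.1 (an exact
  integer-arithmetic criterion, not a heuristic) defines an array of
  `window + p` covered bases. A call requires ≥ 3 copies covering
  ≥ 80% of the sequence. The motif is the per-phase consensus of the
  array, reported in its lexicographically smallest rotation; motifs
  ≤ 6 bp are STRs (microsatellite convention), longer ones generic
  tandem repeats.
* **Mobile elements.** The sequence (both strands) is locally aligned
  (match +2, mismatch −3, gap open −5, extend −2) against each entry of
  a consensus library; the best entry wins if the alignment covers
  ≥ 50% of the query at ≥ 70% identity. The shipped library is
  synthetic (L1-like 2.5 kbp, Alu-like 300 bp, LTR-like 600 bp,
  generated by the simulator) rather than curated repeat-database
  content, avoiding licensing and downloads; users can supply any FASTA
  with `name#CLASS` headers.

Classification precedence for a DEL/INS record: tandem repeat (from
sequence) → mobile element (from sequence) → repeat-region track class
at the locus (STR/Segdup/Satellite/Low_complexity) → `None`. Records
without sequence skip to the track and come back `Unclassifiable` when
nothing covers the locus. Whether "insertions in STR regions" should
be read sequence-based or locus-based is genuinely ambiguous; both
paths exist, with the locus-based path used only when sequence is
absent.

### Breakpoint consequences

Exons and introns are numbered in transcription order (on the minus
strand exon 1 is the genomically last exon), so reported locations
read like standard gene-structure notation. A fusion candidate is any
DEL/DUP/INV/TRA whose two breakpoints fall in two different genes;
same-gene or half-intergenic SVs yield gene-disruption records
instead, and candidates are structural nominations only — no
expression evidence is claimed. For inversions, genes overlapping the
span are reported with the exons trapped fully inside it (a gene
entirely inside the span still has its orientation flipped relative to
flanking sequence, so all its exons are listed); genes merely touched
by a breakpoint are flagged without exon indices. Junction
microhomology is the longest suffix of one flank equal to a prefix of
the other; ≥ 2 bp is hinted as MMEJ-like, an operational cutoff chosen
here (replication-based mechanisms such as MMBIR leave small
insertions/duplications at junctions and are mentioned in free text
only — no classifier is claimed).

## The simulator

The generator emulates the statistical structure of a ~20× paired
tumor/normal long-read SV study so the pipeline can be validated
against known truth:

* **Reference** — 2 chromosomes × 5 Mbp of i.i.d. sequence with 150
  planted STR arrays (motif 1–6 bp, 20–80 copies), ~90 mobile-element
  copies (3′-anchored fragments of the synthetic consensus library,
  mimicking 5′-truncated retrotransposition), a few
  Segdup/Satellite/Low-complexity annotation intervals, and 6
  multi-exon genes per chromosome.
* **Events** — per patient, Poisson-distributed counts around 200
  germline (80 DEL, 80 INS, 15 DUP, 15 INV, 10 TRA) and 50 somatic
  (20 DEL, 15 INS, 5 DUP, 5 INV, 5 TRA) events. Insertions are a
  mixture of STR expansions at planted STR loci (⅓ of insertions at
  baseline), mobile-element fragments (LINE 35%, SINE 20%, LTR 15%)
  and repeat-free sequence. Each STR locus has a characteristic
  expansion size; per-patient draws scatter ±10% around it, so
  expansions of one locus recur across patients — making insertions
  the only strongly recurrent type, as observed in MSI-H colorectal
  cohorts. A fraction 5/21 of patients is MSI-H and their somatic
  STR-insertion mean is multiplied by 20.
* **Observation model** — each emitted call jitters every breakpoint by
  `Normal(0, 100 bp)` and draws support from `Binomial(depth, p)` with
  `p = 0.5` for heterozygous-like germline calls and `p = 0.5 ×
  tumor_purity` (purity default 1) for somatic calls — chosen to
  straddle the ≥ 2-read caller floor and the 0.3× depth filter.
  Germline events are emitted in both members of a pair with
  independent noise; calls below 2 supporting reads vanish. False
  positives (2% of emitted calls, low support `2 + Poisson(1)`) are
  placed uniformly; dropout is 5% on the tumor side and 0 on the
  normal side by default — the zero normal default models the
  lenient ≥ 2-read normal strategy whose purpose is near-complete
  normal recall, and a separate knob exists because the two sides play
  asymmetric roles.
* **Truth ledger** — every emitted call maps to exactly one truth
  event or is flagged as a false positive; recovery metrics define a
  true positive as a somatic call matching a somatic truth prototype
  of the same patient under the default predicate (call-level
  precision, event-level recall).

Two structural simplifications are deliberate. Somatic events are
placed at loci distinct from the same patient's germline events: a
somatic change at a locus already carrying a germline call is not
representable at callset level, and such draws are discarded (they are
rare). Spanning-type (DEL/DUP/INV) lengths are drawn log-uniformly
from 3–300 kbp: with two independently jittered breakpoints the length
noise has σ ≈ 141 bp, and a 3 kbp floor keeps that inside the 20%
length-matching band, mirroring the regime where callset-level
subtraction is statistically reliable. Insertions (single breakpoint,
length carried by the sequence) are immune and span 60 bp–2 kbp.
Deletions carry no sequence — as emitted by long-read callers — so
file-based deletion classification is locus-only and mostly
`Unclassifiable` on this toy genome; classification claims are
validated on insertions, whose planted sequences are recovered at
> 99%.

## What the simulator does not capture

Real genomes are repeat-rich at a density no 10 Mbp toy can represent;
per-sample call totals (tens of thousands pre-filter in real data) and
genome-scale hotspot structure are out of reach, so the simulator
targets *structure* (paired design, germline/somatic asymmetry, MSI
insertion bursts, repeat classes, recurrence concentrated in STR
insertions), not magnitude. Passing recovery tests therefore shows the
pipeline's logic is correct under the stated noise model — not that
real-data precision/recall will match, since real callers produce
correlated errors, segmental-duplication artifacts and multi-allelic
loci the observation model does not emulate. Visual curation of
alignments, population-database annotation and expression validation of
fusions are likewise outside the package's input boundary.

## Numerical and bookkeeping choices

* Coordinates are 1-based inclusive internally (VCF convention); BED is
  converted at the boundary, and the conversion is its own inverse.
* Read support is taken from INFO `RE`, then `SUPPORT`, then the entry
  count of `RNAMES`, accommodating caller version drift.
* Translocations are stored one record per junction, lowest
  (chromosome, position) first; breakend mate pairs collapse to that
  canonical record at ingest, so translocations are counted as events,
  not as mates.
* Negative deletion SVLEN is stored as absolute length; symbolic
  `<INS>` alleles without sequence are accepted (classification then
  reports `Unclassifiable`).
* Cluster ids, representatives and all report tables are deterministic:
  ties are broken by (support, coordinate, sample id), records are
  canonically sorted before clustering, and TSV output is byte-stable
  for fixed input.
* The MSI comparison uses Student's equal-variance two-sided t-test to
  mirror the convention of the figure legends being emulated, with
  Welch's form one flag away; groups with fewer than two samples yield
  `NaN` rather than an error.
* Length histograms use log-spaced bins, 50 bp–10 Mbp at 10 bins per
  decade; inter-SV distance is the gap between consecutive SV starts
  per chromosome per sample, pooled for the cohort overlay.

## Problem sizes

Default test and acceptance runs use the 10-patient cohort on the
2 × 5 Mbp reference (~2,700 truth events, ~650 somatic calls), the
scale at which the full pipeline plus its brute-force oracles completes
in a couple of minutes on one core. Unit tests use a 4-patient,
1.5 Mbp-per-chromosome configuration. All sizes are `SimConfig` fields;
nothing in the code assumes the defaults.

## Known limitations

* The mobile-element aligner reports one class per sequence; chimeric
  or nested insertions are not decomposed.
* The tandem-repeat detector's 10% divergence tolerance merges adjacent
  arrays with different motifs of equal period into one window; the
  per-phase consensus then reports the dominant motif.
* Complete-linkage merging is greedy (insertion-order within candidate
  clusters) rather than globally optimal; single linkage, the default,
  is exact.
* Fusion nomination picks the first gene at a breakpoint when gene
  models overlap; overlapping-gene loci would need transcript-aware
  handling.
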