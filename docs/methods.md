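# Methods

## From alignments to unique insertions

The primary input is a SAM file of transposon-junction reads already mapped
to the reference by an external aligner. The reader (pysam-backed) accepts
only mapped, primary, non-supplementary records with mapping quality at or
above `min_mapq` (default 0 — keep every mapped read; the optional
minimum-read filter on called insertions, below, is the intended noise
control). Duplicate-flagged (0x400) records are kept by default: in Tn-seq,
many independent junction fragments legitimately share coordinates, so
"duplicates" are signal; a switch drops them. A headerless SAM is accepted
only if all records name a single contig (a minimal `@SQ` header is
synthesized); headerless multi-contig input is rejected.

The junction coordinate of a read is its 5′ end: the leftmost mapped base
for a forward read, and for a reverse read the rightmost aligned reference
column, `pos + reference_span(CIGAR) − 1`, where M, D, N, =, X consume
reference and I, S, H, P do not. Soft-clipped bases therefore do not shift
the junction — the junction is the first/last *aligned* reference column,
not the clipped read end. Tools that recompute positions from clipped ends
can differ here by a few bp.

A **unique insertion** is a distinct (contig, junction position, strand)
key; opposite orientations at the same coordinate are distinct insertions
(for a Mariner library the maximum is therefore twice the number of TA
sites). Collapsing the read stream yields the per-library catalog with one
read count per insertion; the catalog's total reads always equals the
number of accepted alignments (a conservation law asserted in the tests).
`filter_low_read_insertions` optionally removes insertions supported by
fewer than `min_reads` reads (default 1, i.e. off), the standard guard
against junctions fabricated by misaligned reads.

## Window scan and window-size selection

`scan_windows` counts unique insertions (default) or reads in windows of
fixed size *W* advanced by `step` (default 10 bp), both strands pooled,
windows starting at coordinate 1. On linear contigs no window passes the
end; on circular contigs windows wrap the origin so every coordinate is
covered equally often. The implementation is prefix-sum/binary-search based
and is checked against per-window brute-force recounting in the tests.

Window-size recommendation follows the empirical pattern that small windows
give an exponential-looking count histogram while sufficiently large
windows give a bimodal one (essential-region windows forming the low peak).
For each candidate size (default 100–2000 bp in 50 bp steps) the histogram
is fit as `frequency ≈ a·exp(−b·count)` by ordinary least squares on
log-transformed frequencies of the positive bins (deterministic, no
initialization; zero bins excluded; at least three positive bins required),
and the smallest size whose R² falls below `r2_cutoff` (default 0.90,
constant in *W*) is recommended. The full R²-by-size table is always
returned, and every downstream entry point takes an explicit window size,
because the recommendation deserves inspection (see Limitations).

`find_bimodal_minimum` locates the classification cutoff in any integer
histogram: frequencies are laid out densely from 0 to the largest observed
value, smoothed with a centered moving average of odd width (default 3;
edges average over the samples that exist), local maxima are found
(scipy.signal, plateaus allowed), the two tallest peaks are taken (leftmost
wins ties), and the count value of the smoothed minimum strictly between
them is returned, smallest value on ties. Fewer than two maxima raises
"distribution not bimodal" rather than guessing.

## Gene scoring

**Truncation.** Each gene's scored span is its *effective interval*: trim
`max(nt_end, floor(pct_end/100 × length))` from each end, strand-aware (on
the minus strand the 5′ trim lowers the end coordinate). Defaults are 5%
at the 5′ end (mis-annotated starts) and 20% at the 3′ end (insertions
there often leave function intact). The nt/pct combination takes the larger
trim — the conservative reading of "a combination of both". A gene whose
trims consume it entirely is flagged, not an error. The central-80%
variant (10% per end) used in some published comparisons is just another
`TruncationPolicy`. Intervals are closed; an insertion exactly on a
truncation boundary counts as inside.

**Essentiality index.** Genes at least as long as the window use the
embedded-max rule; shorter genes the encompassing-min rule (at equality the
single embedded window makes both coincide). Windows are enumerated at
step 1 regardless of the scan step, so EI is phase-independent and exactly
reproducible by brute force. Encompassing windows are clipped to the
contig; in the degenerate case where no window of size *W* can cover the
gene on the contig (annotations running past a contig end), the count of
the largest window containing what fits is used and the gene flagged
`boundary_affected`. EI counts unique insertions by default; a reads mode
exists for saturated libraries. Two caveats are inherent to the method and
surface in the tests: a short essential gene amid non-essential DNA can
receive a high EI (its encompassing windows include flanking insertions),
and filtering insertions can only lower, never raise, any EI.

**Densities.** `insertion_density` divides the effective-interval count
(unique insertions or reads) by either the effective or the annotated
length. `reads_per_ta` divides the read count by the number of TA
dinucleotides in the same interval — the appropriate denominator for
Mariner-family transposons; TA is its own reverse complement, so one strand
is counted. Zero TA sites make the statistic undefined (flagged).

**Classification.** `classify_genes` thresholds any per-gene metric. The
default cutoff is the histogram valley with the strict rule (`metric <
valley`), matching the convention that the valley bin itself belongs to
neither peak; `le` is available. Genes with undefined metrics are excluded
and counted.

**Essential regions.** Windows with count ≤ cutoff are merged when their
intervals overlap or abut, producing annotation-independent candidate
regions (with window count and maximum count per region), exported as a
table or BED (the 0-based half-open conversion happens only at BED
serialization; all in-memory coordinates are 1-based inclusive).

**Score table.** Analyses append named columns to a per-gene table
(`<library>.<metric>`, window size included for EI); existing columns are
never mutated and name collisions get a running suffix, mirroring a
spreadsheet workflow in which each analysis adds a column.

## Library comparison

ΔEI = `min(EI_a, cap) − min(EI_b, cap)` with cap 10 by default: an EI at or
above 10 already says "probably not essential here", so differences beyond
the cap carry no information, and capping keeps ΔEI in [−cap, cap].
Differences (not ratios) are appropriate because EIs are counts in a fixed
window, directly comparable across genes. The selection ratio divides a
gene's reads under the test condition by its control reads; genes with
fewer than `min_unique` (default 3) unique insertions in the control are
excluded as resting on too few independent mutants, and a surviving gene
with zero control reads yields an undefined, flagged ratio. Depth
normalization between libraries is off by default; an optional per-library
scale factor pair is accepted. No formal null model, p-values, or
replicate handling are attempted — the scores are screening statistics.

## The simulator

`simulate_genome` packs `n_genes` non-overlapping genes with log-normal
lengths (median 900 bp, σ = 0.4 — bacterial-like; clipped at 150 bp) onto a
random uniform-composition sequence, intergenic gaps from sorted uniform
breakpoints, strands random, and labels exactly `round(n_genes ×
essential_fraction)` genes essential, drawn without replacement. In
`ta_only` mode the sequence is TA-enriched (~one TA per 8 bp) so
Mariner-style placement has a dense site pool.

`simulate_library` draws candidate sites uniformly over the genome (or
uniformly over TA positions) with random orientation. A candidate inside an
essential gene's *effective interval* (default 5%/20% trims — the same
biological reasoning: 3′ insertions may not disrupt) survives with
probability `essential_leak`, else is redrawn, until `n_unique_insertions`
distinct keys exist. Read counts are drawn from the truncated discrete
power law P(k) ∝ k^(−α) on 1..`max_reads_per_insertion` by inverse CDF
(defaults α = 1.8, max 5000, echoing the reported heavy tail in real
libraries: ~24% singletons alongside insertions with thousands of reads).
Everything is reproducible from `seed` (two independent numpy Generator
streams, `[seed, 0]` for the genome and `[seed, 1]` for the library).

SAM emission writes `read_count` identical perfect-match single-end records
per insertion (50M, MAPQ 60, clipped at contig edges so the junction
geometry survives even within one read length of an end). Mapping noise,
sequencing errors, paired ends and PCR chimeras are deliberately absent:
the simulator tests the analysis, not the aligner. Consequently, passing
recovery tests demonstrate the correctness of the pipeline arithmetic and
the behavior of the scoring rules under depletion + heavy-tailed bias; they
say nothing about robustness to alignment artifacts or genuine biological
hot spots.

## Problem sizes in the test suite

The default test run exercises: brute-force oracle equivalence of the
window scan, interval counts, EI, and region merging on 200 random genomes
of up to 50 kb; a full SAM round trip at 10,000 insertions on a 1 Mb
genome; and a recovery study at 2 Mb / 1,800 genes / 25,000 insertions /
2% leak. The whole suite runs in well under a minute of CPU apart from the
oracle loop (a few tens of seconds).

## Known limitations

* **The constant R² default can recommend too small a window at low
  insertion density.** The log-linear R² of the window-count histogram
  declines with window size even for a completely random library (the
  Poisson bulk sharpens and stops looking exponential), not only when
  bimodality appears. At ~0.0125 insertions/bp the default `r2_cutoff =
  0.90` triggers around W = 200 (≈2.5 insertions per window), where the
  essential and non-essential EI peaks are separated by a valley of only 1
  and leaked insertions in essential genes cost sensitivity; windows of
  300–500 bp separate the populations much better there. This is why the
  R²-by-size table is always reported and the window is everywhere an
  explicit parameter: inspect the histograms before accepting the
  recommendation, exactly as one would with the original interactive
  workflow. Conversely, very large windows degrade short genes via the
  encompassing-min rule.
* The valley finder needs an actual valley; near the transition density the
  EI histogram can fail the bimodality test, in which case no automatic
  cutoff is produced (the pipeline then reports scores without calls).
* No correction for transposon target-site duplication (e.g. the Tn5 9 bp
  duplication), so the two orientations of one physical insertion appear a
  few bp apart.
* Insertion tables, gene tables and the gene_table annotation dialect are
  this package's own tab-delimited formats; GFF3 and FASTA are read through
  gffutils and Biopython. BAM/CRAM are out of scope (convert with
  `samtools view` first).
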