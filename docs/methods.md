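# Methods

## Scope and model

m6akit re-implements, as a tested library, the computational core of an
integrated m6A-RIP-seq + RNA-seq analysis of methyltransferase (METTL3)
silencing: transcript-coordinate window peak calling, metagene peak
profiling, direct/indirect target bookkeeping, an RNA-editing filter
cascade, rMATS post-filters, and RBP/m6A cooperation calls.  Inputs begin at
per-nucleotide coverage, tables and candidate sites; read alignment,
deduplication, variant calling, DESeq2 and rMATS themselves are upstream and
out of scope.

## Coordinates and gene models

All internal coordinates are 0-based half-open; GTF (1-based inclusive) is
converted on read, BED is passed through.  One isoform represents each gene:
the longest by summed exon length (not genomic span), ties broken by the
lexicographically smallest transcript id so selection is deterministic.
Minus-strand transcripts count transcript positions from the genomic right
end.  Noncoding transcripts carry an empty CDS: they participate in peak
calling but are excluded from the three-segment metagene axis, which is
defined only for mRNAs.

## Window caller

Windows are `[s, min(s+100, L))` for `s = 0, 50, 100, ...` while
`s + 50 < L`; a trailing window no wider than the 50-nt step is dropped
because it adds no positions beyond the previous window.  The WinScore
statistic normalizes each library's window mean by that library's gene-median
coverage before taking the log2 ratio, cancelling transcript abundance.

Design points the procedure leaves open, resolved as follows:

* **Enrichment cutoff.** Only windows with WinScore >= 1.0 (two-fold) enter
  testing; the cutoff is exposed (`enrichment_cutoff`).  The BH family is
  the set of tested windows across the whole transcriptome in one batch.
* **Read units.** Fisher's exact test needs counts while the input is
  coverage; window and gene read units are `round(coverage_sum /
  read_length)` with `read_length = 50` (single-end), configurable.
* **Pseudocounts.** One pseudo-read is added to the window and gene totals
  of both libraries (equivalently `read_length` coverage units to window
  sums), keeping scores finite in empty windows.  Transcripts with zero
  median coverage in either library are excluded and logged.
* **Fisher table.** `[[read_win_ip, read_rest_ip], [read_win_ctrl,
  read_rest_ctrl]]`, one-sided toward IP enrichment — the same direction
  WinScore measures.  This equals the hypergeometric tail sum at fixed
  margins, which the tests verify against exact rational arithmetic.
* **Peaks.** Significant windows (adjusted p < 0.05) that overlap or touch
  merge into one peak spanning their union; enrichment score = max window
  WinScore; summit = argmax of per-million-normalized IP coverage, leftmost
  on ties.  Summit flanks of +/-50 nt (<= 101 nt, clipped at transcript
  ends) are extracted for external motif tools.

## Metagene axis

Coding transcripts map to x in [0,3): [0,1) 5'UTR, [1,2) CDS, [2,3) 3'UTR,
each segment rescaled to unit length; x = 2 is the stop-codon boundary.
Peaks are placed by midpoint (summit optional).  When the question is
enrichment *at* the stop codon, histograms should use bin edges that place
x = 2 in a bin interior and bins wider than the band of interest on the CDS
side — with x = 2 on a bin edge the signal splits across two bins, and the
CDS side (denser per rescaled unit whenever CDS > 3'UTR in nt) otherwise
always wins.  The drivers use `np.linspace(0, 3, 9)` for mode checks and 16
bins for uniformity checks.  Stop-codon offsets are `summit − cds_end_tx`
(negative = upstream).  Consensus-site counting uses IUPAC matching with
overlaps allowed; the default motif is RRAC (the canonical m6A core), with
GACPyC-style patterns available through the motif argument.  Degenerate rank
correlations (constant scores or counts) are reported as None.

## Target bookkeeping

Per control peak: *lost* (no overlapping silenced peak), *reduced*
(overlap, enrichment drop >= 1.0 log2 units — symmetric with the caller's
cutoff, configurable), *common* (overlap within the threshold),
*independent* (silenced-only, or overlap with silenced score higher by the
threshold).  Overlap means >= 1 shared nt on the same transcript.  A gene's
class is its strongest peak class (lost > reduced > common > independent).
DE regulation uses strict inequalities (adjusted p < 0.05, |FC| > 1.5).
Direct targets = lost/reduced genes, split by the DE flag; indirect
regulated = regulated without lost/reduced peaks; the four target classes
partition the gene universe, and all percentages guard zero denominators.
Distribution comparisons (abundance, fold change, RBP deltas) default to
the two-sample KS test with asymptotic p; Wilcoxon rank-sum is available
where medians are the right summary (and is the default for the per-type
splicing comparisons).

## Editing cascade

SNP-mask removal applies to every candidate.  Alt-supporting reads whose
mismatch lies in the first six read bases are discounted before counting
(random-hexamer priming artifacts); the 0.1 minimum alt frequency is
evaluated on post-discount counts.  The remaining filters — support (>= 3
alt reads, frequency >= 0.1), simple repeats, <= 4 bp from a splice
junction, reference homopolymer runs >= 5 covering the site, and a
high-similarity mask — apply to non-Alu sites only (`strict_all` extends
them to Alu sites).  The similarity filter consumes a user-supplied mask
BED rather than running an aligner.  `filter_status` records the first
failing filter in cascade order and is independent of input order.
High-confidence events have >= 10 reads and ratio >= 0.2, both inclusive.
Event typing follows standard chemistry on the transcript strand (A->G =
A-to-I, C->T = C-to-U; strandless sites admit both genomic orientations).
Region annotation uses CDS > UTR > intronic > intergenic precedence and
substitutes the alt base into the reference codon under the standard code
for synonymous/nonsynonymous calls.

## Splicing post-filters

Retained events need FDR < 0.05, |inclusion difference| >= 0.05 (five
percentage points of PSI — the only reading consistent with PSI in [0,1]),
and inclusion and skipping counts >= 10 in each condition, summed over
replicates.  Filtering is idempotent.  Exon-skipping m6A dependence compares
inclusion differences between events on m6A-modified vs unmodified genes
(KS) and flags skipped exons overlapping genome-projected control peaks.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
reads: per-nt coverage is negative-binomial (mean 30, dispersion 0.3 —
var = m + 0.3 m^2) over synthetic architectures (5'UTR 100–300 nt, CDS
300–1200 nt, 3'UTR 150–500 nt, 1–4 exons, 10% noncoding), with a shared
per-gene lognormal expression factor in IP and input.  IP enrichment is
planted by multiplying the IP mean by `peak_fold` (default 4) inside one
interval per chosen gene (20% of genes).  Planted intervals live on the
caller's window lattice — widths 100/150/200 nt, starts on the 50-nt grid —
matching the scale at which the window scan can localize a peak; with
free offsets the union-of-windows merge rule admits boundary overhangs up to
~66 nt, which says something about window quantization, not about the
caller's sensitivity.  Silenced-condition structure mirrors the study's
reported proportions, chosen once: ~2.3% of control peaks stay common,
~1.2% are reduced (planted at control fold 12 vs silenced fold 3 so that the
reduced peak is still callable but >= 1 log2 unit lower), the rest are lost,
and 3% of genes gain silenced-only peaks.  The DE table shifts peak-bearing
genes by −1.5 log2FC (noise sd 0.3) and centers others at zero, with small
adjusted p exactly for genes whose drawn |log2FC| clears the 1.5-fold line —
so a zero effect produces a genuine null table.  The editing fixture plants
50 true sites (72% in Alu) plus 10 decoys per filter class, each violating
exactly its own filter; the "first six bases" decoy necessarily surfaces as
a support failure after discounting.  A 37% event loss is planted in the
silenced condition.  The rMATS fixture plants 30 significant SE events
(negative inclusion difference: inclusion rises when the methyltransferase
is silenced), 80% on m6A genes; all other events fail at least one filter.
RBP fixtures shift site-bearing groups by +/-1 log2 unit at n = 200 per
group.

What the generator does *not* model: read-level autocorrelation of coverage
(adjacent positions share reads), sequence-content and fragment-length bias,
multi-isoform expression, and correlated replicate structure.  Null
false-peak rates measured here are therefore optimistic relative to real
libraries, where coverage noise is locally correlated; passing tests
demonstrate correctness of the statistics and bookkeeping, not calibration
on real data.

## Numerical choices and limitations

BH adjustment is the standard step-up with enforced monotonicity, verified
against a quadratic-time reference and statsmodels.  Fisher p-values come
from `scipy.stats.fisher_exact` (one-sided), verified against exact
`Fraction` tail sums for margins up to 60.  Summit ties break leftmost;
peak midpoints at segment boundaries belong to the downstream segment.
All simulation randomness flows through `numpy` Generators seeded as
`[seed, stream]` per component, so outputs are reproducible per seed and
components are independent.  Problem sizes in the drivers and acceptance
script (200 genes, 2000 metagene positions, 100 RBPs, 400 sampled Fisher
tables) are the package's default desk-scale study; they keep every stage
exact or well-powered while remaining quick to run.
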