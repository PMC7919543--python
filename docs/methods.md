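# Methods

This note documents the models and procedures implemented in
`edna-profiler`, the defaults they use, and what the synthetic experiments
do and do not demonstrate.

## The assignment problem at a short barcode

The 12S-v5 fragment is ~98 bp. Across a regional freshwater fish fauna,
reference sequences of different species routinely differ by 0–2
substitutions, while per-base sequencing error on an amplicon run is of
order 1–3%. A read therefore has a non-trivial probability of aligning
equally well, or better, to a heterospecific reference. The pipeline's
position is that this error should be *simulated and measured* against the
actual reference database, and species that cannot be separated reliably
should be reported as multi-species bins rather than as false precision.

## Alignment model and the G/M/L statistics

Reads are aligned locally (Smith–Waterman) against every reference with
match +2, mismatch −3, gap open −5, gap extend −2 (the open score applies
to the first gapped base). These weights are conventional short-read
local-mapping values; they are configurable and recorded in run metadata.
The engine is Biopython's `PairwiseAligner`; an exact pruning layer skips
references using the bound

    SW score ≤ |read| + |ref| − editdistance(read, ref),

which holds because every edit removes at least one potential match column
and matches score +2. Edit distances come from edlib. Pruning preserves
exactness (bounds are scanned in decreasing order until no bound can reach
the best observed score, so equal-scoring ties are still enumerated);
a property test checks the search against a brute-force DP oracle.

The single best-scoring reference is reported. Ties are broken by the
lexicographically smallest accession and flagged; determinism matters
because tie direction shapes the misassignment graph.

Each alignment is reduced to:

* `G`: number of gap *events* — insertion runs, deletion runs and edge
  skips each count once, regardless of length. The alternative reading
  (counting gapped bases) exists; the event interpretation is consistent
  with counting a multi-base edge skip as a single gap position, and is
  the one implemented.
* `M`: number of mismatch positions within match columns.
* `L`: reference length minus read bases in match columns, floored at 0.
  Insertions do not contribute aligned bases; `L` penalizes incomplete
  reference coverage and truncated reads, which `G` alone does not.
  Insertions beyond the reference length could drive the raw difference
  negative, hence the floor.

Thresholds default to `G ≤ 3, M ≤ 3, L ≤ 3`, boundary-inclusive. The
filter tally attributes each rejection to the first violated criterion in
the order G, M, L. Reads are dereplicated at 100% identity before
alignment and counts re-expanded afterwards.

External alignments are ingested from SAM text. CIGAR and MD are decoded
together so mismatch positions land in read-cycle coordinates: MD consumes
match/deletion columns only, so insertions and soft clips shift the cycle
index. Hard clips are treated as edge skips with a warning (the clipped
bases are not present in the stored sequence, but the skip still counts
toward `G`).

## Error model

Per-cycle substitution rates are estimated from reads that map
unambiguously: species separated from all heterospecifics by ≥28 bits,
with ≥2 reference accessions (so genuine intraspecific variation does not
masquerade as error) and deep mapped-read counts. Bit scores use
`(λ·S − ln K)/ln 2` with λ = 1.28, K = 0.46, ungapped-equivalent constants
for +2/−3 scoring; both are configurable. References with fewer than 5
mapped unique reads, or with any site above a 10% mismatch rate (likely a
true polymorphism), are excluded from pooling.

Polynomials of order 0–5 are fitted by OLS to the pooled per-cycle
proportions over cycles 10–90 (read edges are idiosyncratic: skips,
residual adapter, reference length variation). Order is selected by the
Gaussian least-squares AIC, `n·ln(RSS/n) + 2(k+1)`. AIC is liberal: on
pure binomial noise around a straight line it occasionally admits a cubic
whose extra coefficients are numerically negligible; the round-trip test
therefore checks recovered *rates*, not the selected order alone. The
fitted curve is extrapolated over all cycles for simulation use and
clipped to [0, 1].

The default simulation profile is linear — 0.66% at cycle 1 to 2.96% at
cycle 98 — a realistic MiSeq amplicon error gradient, with 20% of error
events realized as 1-bp indels (insertion or deletion with equal odds),
mirroring the substitution:indel convention of common read simulators.
The indel fraction is a free parameter, not estimated from data.
Homopolymer-specific error and quality-score modeling are out of scope;
FASTQ output carries constant Q30 placeholders.

## Misassignment binning

Equal numbers of reads are simulated per accession (an equal-abundance
assumption), mapped back, filtered at G=M=L=3, and tabulated as a directed
graph: weight(q→r) is the fraction of query species q's simulated reads
assigned to species r. Query species with total misassignment strictly
above 5% are retained; edges strictly below 1% of that query's total error
are dropped; surviving edges are read undirected and connected components
become bins. Species sharing byte-identical references are grouped a
priori (transitively) and merged in regardless of simulated error, with
provenance recorded separately (`a-priori` vs `error-based` vs `merged`).
Unmapped simulated reads are excluded from the overall-error denominator
and reported as a separate rate: assignment error is a property of reads
that mapped.

## Contamination and censoring

Index crosstalk (reads demultiplexed to the wrong library) is estimated
from negative controls under a pooled binomial model: each read hops with
probability *r* to another library, uniformly by default (exposure share
`n_controls/(n_samples−1)`; a library-size-weighted share is available).
The pooled MLE is observed control counts over total exposure. A taxon is
flagged as a point contaminant when its control count exceeds the binomial
99.9% quantile, Bonferroni-corrected over taxa, with the dominant control
sample identified — a statistical replacement for what is often judged by
eye. Flagged taxa are removed from every downstream quantitative product;
the removal is logged, never silent.

Censoring masks cells strictly below 0.1% of their library ("at least
0.1%" detections survive) and excludes libraries under 1,500 mapped reads
from quantitative analysis. Library size is judged on the full mapped
totals *before* contaminant removal: a flagged taxon invalidates its
reads' taxonomic meaning, not the library's sequencing depth. Raw and
censored tables are both kept, with the mask recorded.

## Compositional analysis

Counts are compositional, so per-sample proportions (renormalized over the
bins detected in that sample) are centered-log-ratio transformed:
`clr(p_i) = ln p_i − mean_j ln p_j`, which sums to zero per sample. Zeros
are structural here (censored or absent) and are excluded from the
geometric mean rather than imputed; a multiplicative zero-replacement
alternative would be a reasonable variant but is not the default because
the positive-part convention matches how positive-sample summaries are
defined downstream. A single dataset-wide scalar, `−min(CLR) + 0.01`, is
added to detected cells so all detections are positive; the scalar is
recorded on the table because summed compositions shift by
`n_positive × scalar` under any other choice — sums are only comparable
within a run.

Bin summaries (summed and average composition over positive samples,
ranks), the log(CPUE) correlation (Pearson with t-distribution p-values at
n−2 df, plus Spearman), replicate concordance, site contrasts and the
Ward-clustered (on 1 − ρ) Spearman sample matrix all operate on this
table. CPUE is rescaled to percentages before the log purely for plotting
convention; a constant multiplier cannot change the correlation, and the
implementation asserts that.

## The synthetic watershed

The generator's fixed scenario stands in for a real survey's raw data and
defines the conditions under which the pipeline is exercised:

* **References**: 30 species, 35 accessions, 98 bp. Species groups are
  founded ~8 substitutions from a common ancestor (between-group
  divergence ~14–16%); within groups the structure is exact: two
  identical-sequence pairs (a-priori bins), six congener pairs one
  substitution apart at cycles spread over the read (confusable but below
  the 5% binning threshold), a radiating complex whose four satellite
  accessions sit one substitution from a central haplotype assigned to a
  different species (driving that species past 5% — the error-based bin),
  three two-substitution satellites, and two isolated species with a
  second conspecific accession (the substrate for error-rate estimation).
  Scaled against a regional database of ~110 species / ~240 accessions,
  this keeps roughly the same proportion of species in multispecies bins.
* **Communities**: log-skewed lognormal abundances (σ = 1.3, so the top
  few taxa hold most reads), two site groups with four species restricted
  to one side of a barrier, 10 biological samples plus 2 technical
  replicate pairs and 3 negative controls, index crosstalk 1e-4, a
  500-read point-contamination spike into one control, and per-taxon
  replicate dropout probability 0.2.
* **CPUE**: lognormal noise (σ = 0.5) around true read totals.

Simulations in the tests and acceptance script run at 600–1,500 reads per
accession and 2,000–3,000 reads per library — sizes chosen so the binomial
error of every estimate is far below its assertion tolerance while the
whole suite stays desk-scale. Under these conditions the overall
assignment error after binning is ~0.6%, of the same magnitude as the
~0.8% a real regional database yields, though the exact value is a
property of this scenario's divergence structure, not a universal
constant.

What passing these tests shows: the statistics are implemented correctly,
the estimators recover their generating parameters, and the binning rules
behave as designed under a realistic error profile. What they do not
show: robustness to PCR chimeras, amplification bias, quality-dependent
error, reference databases with wrong taxonomy beyond the simulated
cases, or paired-end artifacts — none of which the generator emulates.

## Numerical and degenerate-input conventions

* Dereplication keeps the lexicographically smallest accession;
  idempotent by construction.
* K2P distance returns `inf` outside the model's valid range
  (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`); sites with gaps or N are excluded, and
  unequal ungapped lengths are an error directing the caller to align
  first.
* A species with a single accession has an undefined conspecific score
  minimum and is ineligible for error estimation rather than zero-filled.
* An all-equal rate table short-circuits to an order-0 model with a note.
* Samples with fewer than two detected bins have no defined log-ratio and
  are dropped with a warning.
* Empty edge cases (no negative controls, no replicate pairs, empty
  tables) warn and return empty results instead of raising, except where
  silence would corrupt downstream totals (orphan accessions, unknown
  sample labels and unknown read ids are errors).
* All randomness flows from one integer seed through labeled
  `SeedSequence` spawn keys (CRC32 of an operation label), so components
  are independent but bitwise reproducible.
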