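# edna-profiler

Error-aware taxonomic profiling for 12S rRNA eDNA metabarcoding of fish
communities.

Environmental DNA (eDNA) surveys amplify a short barcode locus — here the
~98-bp 12S-v5 mitochondrial fragment — from filtered water and assign the
resulting amplicon reads to a curated reference database to profile which
fish are present and in what relative amounts. At this marker length many
congeners differ by zero, one or two substitutions, so sequencing error
alone can move reads between species. This package implements a pipeline
built around that problem, for researchers and fisheries managers who want
assignments whose error is *quantified* rather than assumed:

* **Reference curation** (`refdb`): dereplication at 100% identity within
  species, terminal-gap filtering of incomplete sequences (threshold nine
  positions, with exemptions for genuinely short taxa such as lampreys), an
  advisory Kimura two-parameter divergence screen for misidentified
  accessions (conspecifics >13% divergent), and per-species
  conspecific/heterospecific alignment bit-score separation.
* **Mapping stringency as explicit alignment anatomy** (`align`): reads are
  locally aligned (Smith–Waterman, best hit, lexicographic tie-breaking
  with an ambiguity flag) and each alignment is reduced to three integers:

  * `G` — distinct gap positions (one per indel run; an edge skip of any
    length counts once),
  * `M` — mismatch positions,
  * `L` — reference length minus read bases in match columns (coverage
    shortfall),

  with a read retained when `G ≤ 3, M ≤ 3, L ≤ 3`. The same statistics are
  reconstructed from external SAM alignments via CIGAR + MD parsing.
* **Error-rate estimation** (`errormodel`): per-cycle mismatch proportions
  from unambiguously mapped reads (well-separated species, ≥2 accessions,
  deep coverage), fitted by polynomials over cycles 10–90 with the order
  chosen by AIC. The default profile is linear, 0.66% at cycle 1 rising to
  2.96% at cycle 98.
* **Misassignment binning** (`binning`): reads are simulated from every
  accession under the fitted error model and mapped back. Species whose
  total simulated misassignment exceeds 5% (edges below 1% of a query's
  total error dropped) are joined into taxon bins by connected components,
  merged with a-priori bins of species whose references are identical.
* **Counts QC** (`countsqc`): bin × sample count tables; index-crosstalk
  rate estimated from negative controls under a pooled binomial model with
  contaminant flagging (point contamination); censoring of cells below
  0.1% of a library and libraries below 1,500 mapped reads; per-reference
  mismatch histograms that expose hidden haplotypes as multimodality;
  greedy centroid clustering of residual reads; correlated-bin detection.
* **Compositional analysis** (`composition`): centered log-ratio transform
  over detected bins plus a recorded positivity scalar; per-bin
  summed/average compositions and ranks; correlation of summed composition
  with log(CPUE) from capture surveys; technical-replicate concordance and
  dropout; site contrasts across a barrier; Ward-clustered sample
  correlation matrices; eDNA-versus-capture concordance classification.
* **Synthetic data** (`synth`): a first-class generator for reference sets
  with controlled divergence structure (including identical cross-species
  sequences and a radiating haplotype complex), reads with the
  position-dependent error profile, log-skewed multi-sample communities
  with 1e-4 index crosstalk, spiked negative controls and
  technical-replicate dropout, and CPUE tables lognormally noised around
  true abundances.

The package also ships the published per-bin summary tables of a St. Regis
River (NY) 12S survey with matched capture CPUE (`surveydata`), used as a
real dataset for the desk statistics.

## Worked example

Build the synthetic watershed reference set, simulate 1,000 error-bearing
reads per accession, map them back and derive taxon bins:

```python
from edna_profiler import binning, synth

db = synth.watershed_reference_db(seed=1)
print(f"{len(db)} reference accessions for {len(db.species)} species")

model = synth.ErrorModel.study_default()
assignments, truth = binning.simulate_assignment_error(
    db, model=model, n_per_accession=1000, seed=1)
graph = binning.build_graph(assignments, truth)
bins = binning.prune_and_bin(graph, binning.bin_identical(db),
                             species=sorted(db.species_index))
res = binning.overall_error(assignments, truth, bins)
print("multispecies bins:")
for b in bins.multispecies_bins():
    print(f"  {bins.provenance[b]:>11}: {sorted(bins.bins[b])}")
print(f"overall assignment error: {res['overall_error']:.2%} "
      f"({res['n_mapped']} mapped reads)")
print(f"unmapped under G=M=L=3:   {res['unmapped_rate']:.2%}")
```

prints

```
35 reference accessions for 30 species
multispecies bins:
     a-priori: ['Coregonus_minor', 'Coregonus_parvus']
     a-priori: ['Lampetra_sima', 'Lampetra_simillima']
  error-based: ['Notropis_medius', 'Notropis_radians']
overall assignment error: 0.52% (33131 mapped reads)
unmapped under G=M=L=3:   5.34%
```

Reading the output: the two species pairs with byte-identical references
can never be separated by mapping and are binned a priori; the radiating
haplotype complex (`Notropis medius`/`N. radians`, whose accessions
surround the central haplotype at single substitutions) leaks more than 5%
of its simulated reads and is binned from the misassignment graph. After
binning, roughly one read in 200 is still assigned outside its source bin
— the residual error contributed by congener pairs one substitution apart
that stay below the 5% binning threshold. About 5% of simulated reads
carry more than three mismatches and are rejected by the stringency
filter, not misassigned.

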