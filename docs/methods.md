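# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and BED/bedGraph (0-based half-open) are converted at the I/O boundary
only; reading an annotation and writing it back preserves the printed
1-based coordinates exactly. FASTA is read with Biopython, SAM/BAM with
pysam. Accepted GFF3 is the flat bacterial subset: one feature per row
(`gene`, `CDS`, `rRNA`, `tRNA`, `tmRNA`, `ncRNA` by default), strand
required, no spliced parent/child structure.

## Coverage

Raw coverage at a position is the number of primary mapped reads on that
strand whose aligned reference span covers it. CIGAR M/=/X/D consume
reference and count as covered (bacterial data has no splicing; deletions
are treated as covered), N consumes without coverage, S/I/H consume none.
Secondary and supplementary alignments are excluded. Paired-end mates are
counted independently; fragment-span inference is out of scope.

Normalization is counts per million (CPM): values × 10⁶ / total mapped
primary reads of the sample, both strands. The total is per sample, not
per strand, so the two strands of one library share a scale. Normalizing
twice is an error, never a silent rescale. Replicates are averaged
positionwise after normalization.

Strand assignment assumes read strand = transcript strand;
`reverse_stranded` flips it for dUTP-style libraries.

## Candidate detection

Within each intergenic interval the detector computes two tracks from the
averaged condition coverages *a*, *b*:

* expression: positionwise max(a, b) — "expressed in at least one
  condition";
* differential expression: fold(p) = max((a+ε)/(b+ε), (b+ε)/(a+ε)) with
  pseudocount ε (default 1.0 CPM). The symmetric form treats induction and
  repression alike, matching the downstream use of |log2 FC|, and is
  defined at zero coverage.

A candidate peak is a maximal expression run (≥ `min_expression` for
≥ `min_expression_run` nt) that intersects at least one differential run
(≥ `fold_change` for ≥ `fold_change_run` nt); the peak's coordinates are
the expression run's. Peaks shorter than `min_region_length` (200 nt) are
expanded symmetrically about their midpoint (odd deficit: extra nt on the
right), clipped to chromosome bounds only — an expanded region may overlap
annotation, which is flagged (`overlaps_annotation`), not rejected, since
predicted boundaries routinely overshoot true transcript ends. Peaks whose
gap is ≤ `merge_gap` (50 nt; the boundary case gap = 51 does not merge)
are merged to a fixpoint. `merge_order` selects expand-then-merge
(default) or merge-then-expand; the two differ only when expansion closes
a gap that merging alone would not.

Intergenic masking: a position is intergenic on strand s if no feature on
strand s covers it; rRNA/tRNA mask both strands by default
(`mask_both_strands_for_structural_rna`), because antisense reads over
structural RNA loci are predominantly library artifacts. The flag exists
because a strand-blind complement is equally defensible for sparse
annotations.

Thresholds are interpreted in normalized (CPM) units, since normalization
precedes filtering; pass raw tracks together with raw-unit thresholds to
reproduce pipelines that filtered before normalizing. The calibrated
preset `zmobilis-aerobic` is (M = 34, L_M = 24 nt, F = 2.7, L_F = 15 nt).
`suggest_criteria` derives data-driven defaults: M and F are the means of
the expression and fold tracks over intergenic positions covered in at
least one condition (the support restriction keeps vast zero-coverage
stretches from dragging the means to zero), with 15-nt run lengths.

### A note on threshold monotonicity

Tightening `fold_change`, `min_expression_run` or `fold_change_run` can
only reduce the peak count. Tightening `min_expression` shrinks the set of
positions covered by peaks but can *increase* the count, because one long
run can split into two runs that each still pass the length filter. The
test suite asserts exactly these two statements.

## Target prediction

For every gene the target window runs from 200 nt upstream of the
translation start through 100 nt downstream of it (start codon's first nt
at relative offset 200; 300 nt total unless clipped by chromosome ends),
reverse-complemented for minus-strand genes. Windows deliberately ignore
neighbouring annotation: ribosome-binding-site occlusion sites live there
regardless of gene density.

The built-in scorer is a local antiparallel hybridization dynamic program:
base pairs contribute fixed energies (GC −3.0, AU −2.0, GU −1.0 kcal/mol;
`gu_wobble` can disable wobble pairs) and every interior loop/bulge is
charged `loop_open` (+4.0) once plus `loop_extend` (+0.5) per unpaired
nucleotide on either strand. An interaction is reported only if the
optimum has ≥ `min_duplex_len` (6) pairs and negative energy; ties in the
optimum prefer more pairs. This model has no stacking, no accessibility or
unfolding terms, and its absolute energies are not thermodynamic — its
contract is a reproducible total order of gene windows per candidate.
Where calibrated energies matter, run a dedicated interaction predictor
over the FASTA files the pipeline writes (candidate sequences and target
windows) and feed its CSV/TSV output back through the external adapter
(columns query id / target id / energy; positive-energy rows are dropped
with a warning). T and U are interchangeable on input.

Per candidate, the top k = 50 targets are kept, sorted by energy ascending
with gene-id tie-breaks, so rankings are deterministic.

## Differential expression and scoring

Counting: a primary mapped read increments every same-strand feature
(gene or candidate region) its aligned span overlaps by ≥ 1 nt — a
deliberately simple overlap mode; a read spanning two features counts for
both.

Size factors are median-of-ratios: factor_j = median over features with
all-positive counts of count_ij / geometric mean of feature i. The median
is taken in linear space. The log2 fold change of feature i is
log2((count_iB/factor_B + ε) / (count_iA/factor_A + ε)) with ε = 1 by
default (0 is allowed when all counts are positive); replicate samples of
a condition are averaged after size-factor normalization. No dispersion
estimation, shrinkage or significance testing is attempted: with single
replicates per condition those estimates are degenerate, and the score
consumes only the fold-change point estimate.

Scores per candidate: raw sRNA component |log2 FC| of the candidate's own
counts; raw mRNA component Σ |E_t|·|log2 FC_t| over its top-50 targets
(genes absent from the count matrix contribute 0). Both columns are
normalized by their maximum over candidates (an all-zero column stays
zero, with a warning), summed into the phenoscore ∈ [0, 2], and ranked
descending with ties broken by sRNA score, then genomic position. The
absolute-value convention makes strong binding and large expression change
both increase the score regardless of direction; `signed_mrna_terms`
preserves the literal signed product E·log2FC for sensitivity analysis.

## Synthetic data

The generator emulates a small bacterial chromosome: uniform-random
sequence; non-overlapping genes (600–1200 nt) on alternating strands with
uniform slack between them; sRNAs planted midway in distinct inter-gene
gaps, so every planted locus is fully intergenic on both strands. Genes
get per-condition means (uniform 40–200 per-nt coverage, log2 fold changes
~ N(0, 1)); planted sRNAs get a high-condition mean (120) and the
configured fold (10), with the induced condition chosen at random per
locus. Per-nucleotide counts are drawn per replicate from Poisson (or
negative binomial, dispersion 0.1) around background (rate 2) plus
transcript means. Optional synthetic reads are uniform-start 50-nt
single-end alignments within transcripts, written as SAM.

Track-based simulation marks tracks as normalized under a nominal library
of 10⁶ reads, so CPM is numerically the identity and planted means share
units with the filter thresholds. The simulator does not model sequencing
error, positional/GC bias, operonic read-through or paired-end structure —
passing recovery tests therefore demonstrates the pipeline's logic under
calibrated count noise, not performance on real libraries.

The recovery presets plant sRNAs of 100–300 nt rather than the full
50–300 nt class range: a perfectly detected locus of length L has interval
Jaccard at most L/200 against its ≥200-nt expanded region, so loci under
100 nt can never reach the 0.5 recovery threshold regardless of detection
quality. Recovery is measured by same-strand interval Jaccard ≥ 0.5
(recall over planted loci, precision over predictions; no predictions
reports precision 1.0 vacuously, with a warning).

## Problem sizes and determinism

The shipped simulations use a 50-kb genome, 20 genes and 5 planted sRNAs —
large enough that intergenic search, merging, windowing, counting and
ranking are all non-trivial, while a full pipeline run (≈ 45k simulated
reads per condition, builtin target scoring for every candidate×gene pair)
completes in well under a minute. All randomness flows from a single seed
through `numpy.random.default_rng`; identical inputs and configuration
give bit-identical candidate BEDs and ranked tables, which the test suite
asserts.

## Known limitations

* Candidate boundaries are peak-run boundaries, not transcript ends; 5′/3′
  refinement (RACE-style) is out of scope.
* The built-in energy model is ordinal, not thermodynamic; use the
  external adapter when energies must be interpretable.
* Two-condition designs only; no significance statements accompany the
  fold changes.
* Full-scale application to the *Z. mobilis* aerobic/anaerobic public
  dataset (the setting the `zmobilis-aerobic` preset was calibrated for)
  requires downloading the SRA runs and an external interaction predictor,
  and is not part of the offline test suite.
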