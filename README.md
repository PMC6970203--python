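# srnarefine

Phenotype-informed discovery and ranking of bacterial small RNAs (sRNAs)
from dual-condition RNA-seq.

Bacterial sRNAs (typically 50–300 nt, often intergenic) are global
regulators and attractive handles for strain engineering, but most genomes
carry hundreds of unannotated candidates and almost no functional
information. Given strand-specific RNA-seq from two growth conditions that
bracket a phenotype of interest (e.g. aerobic vs. anaerobic growth as a
proxy for low vs. high ethanol), `srnarefine`:

1. **finds candidate sRNA regions** — intergenic intervals that are both
   expressed and differentially expressed between the conditions
   (`scout` stage), and
2. **ranks them by predicted phenotype relevance** — combining each
   candidate's own expression change with the expression changes of its
   predicted mRNA targets, weighted by predicted binding energy
   (`score` stage).

## The method

**Candidate detection.** Per-nucleotide, per-strand coverage is computed
for each sample, normalized to counts per million mapped reads (CPM), and
replicate-averaged per condition. Within every intergenic interval
(same-strand complement of the annotation; rRNA/tRNA mask both strands by
default), a *candidate peak* is a maximal run of ≥ *L_M* consecutive
positions with coverage ≥ *M* in at least one condition that intersects a
run of ≥ *L_F* positions with direction-symmetric fold change ≥ *F*, where

fold(p) = max( (a+ε)/(b+ε), (b+ε)/(a+ε) )

for averaged coverages *a*, *b* and pseudocount ε. Peaks shorter than
200 nt are expanded symmetrically to 200 nt, and peaks within 50 nt of each
other are merged into single candidate regions (`possRNA<n>` /
`negsRNA<n>` by strand). The calibrated preset `zmobilis-aerobic` uses
*M* = 34, *L_M* = 24 nt, *F* = 2.7, *L_F* = 15 nt; `suggest_criteria`
derives thresholds from dataset means (15-nt runs) for other data.

**Ranking.** For candidate *i* with read counts normalized by
median-of-ratios size factors:

- sRNAscore_i = |log2 FC_i| / max_j |log2 FC_j|
- mRNAscore_i = ( Σ_{t ∈ top-50 targets(i)} |E_t| · |log2 FC_t| ) / max_j (…)
- **phenoscore_i = sRNAscore_i + mRNAscore_i ∈ [0, 2]**

where E_t is the predicted sRNA–mRNA binding energy (kcal/mol) against the
−200…+100 nt window around each gene's translation start. Energies come
either from a built-in local hybridization model (base-pair energies with
affine loop penalties — a fast, deterministic stand-in that only needs to
order targets) or from a dedicated interaction predictor such as IntaRNA
via the tabular adapter (`--engine external`). Candidates are reported in
descending phenoscore order.

## Worked example

Everything below runs offline on a seeded synthetic dataset (50-kb genome,
20 genes, 5 planted intergenic sRNAs at 10-fold differential expression,
Poisson count noise):

```bash
refine simulate --seed 42 --preset small --out demo
refine scout \
    --genome demo/genome.fasta --annotation demo/annotation.gff3 \
    --cond-a-plus demo/condA.plus.bedgraph --cond-a-minus demo/condA.minus.bedgraph \
    --cond-b-plus demo/condB.plus.bedgraph --cond-b-minus demo/condB.minus.bedgraph \
    --preset zmobilis-aerobic --out-prefix demo/candidates
# -> 5 candidate regions -> demo/candidates.bed
head -3 demo/candidates.bed
# chr1   645     868     possRNA1        0       +
# chr1   17882   18148   possRNA2        0       +
# chr1   7913    8145    negsRNA1        0       -
```

All five planted loci (see `demo/truth.tsv`) are recovered; e.g. `possRNA1`
overlaps the planted `srna01` at chr1:645–868 almost exactly. A full run —
coverage from alignments, candidate search, built-in target prediction,
counting, scoring — from a YAML config:

```bash
cat > demo/config.yaml <<EOF
genome: demo/genome.fasta
annotation: demo/annotation.gff3
condition_a: aerobic
condition_b: anaerobic
alignments_a: [demo/condA.sam]
alignments_b: [demo/condB.sam]
output_dir: demo/out
criteria:
  min_expression: 750.0   # CPM units of this ~46k-read library (~1/3 of planted signal)
EOF
refine run demo/config.yaml
cat demo/out/phenoscores.tsv
# sRNA      mRNAscore  sRNAscore  Phenoscore  Rank  5'-end  3'-end
# negsRNA1  0.958      1.000      1.958       1     8135    7924
# possRNA2  1.000      0.940      1.940       2     17892   18140
# possRNA1  0.903      0.947      1.850       3     655     858
# negsRNA2  0.901      0.928      1.829       4     25244   25045
# negsRNA3  0.907      0.889      1.796       5     37248   37049
```

Each row is one candidate: its normalized target-weighted score
(mRNAscore), its own differential-expression score (sRNAscore), their sum
(Phenoscore, the ranking key), and strand-oriented 1-based genomic ends
(5′ > 3′ on the minus strand). Here the five planted sRNAs occupy ranks
1–5, as they should: they were simulated with the strongest condition
response.

The same stages are available as library functions
(`srnarefine.scout.scout`, `srnarefine.phenoscore.score_candidates`, …);
the CLI is a thin wrapper.

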