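"""Candidate scoring and ranking.

Each candidate region receives three numbers:

* ``srna_score`` — |log2 fold change| of the candidate's own read counts
  between the two conditions, normalized by the maximum over candidates;
* ``mrna_score`` — sum over the candidate's top-k predicted mRNA targets of
  |binding energy| x |target log2 fold change|, normalized the same way;
* ``phenoscore`` — their sum, in [0, 2]; candidates are ranked by it.

Differential expression uses median-of-ratios size factors and a
pseudocounted log2 ratio.  With single replicates per condition, dispersion
estimation is degenerate, so no shrinkage or significance testing is
attempted: the score consumes only the fold-change point estimate.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .scout import CandidateRegion
from .targets import TargetPrediction
from .genome import Feature, MINUS, PLUS

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    log2fc: float  # condition B over condition A


@dataclass
class ScoreRecord:
    srna_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    raw_srna: float = 0.0
    srna_score: float = 0.0
    raw_mrna: float = 0.0
    mrna_score: float = 0.0
    phenoscore: float = 0.0
    rank: int = 0


def count_reads(
    alignment_paths: dict[str, str | list],
    features: list[Feature],
    reverse_stranded: bool = False,
) -> pd.DataFrame:
    """Count matrix (features x samples) by simple strand-aware overlap.

    A primary mapped read increments every same-strand feature its aligned
    span overlaps by >= 1 nt (a read over several features counts for each).
    ``alignment_paths`` maps sample name -> SAM/BAM path.
    """
    index = [f.id for f in features]
    matrix = pd.DataFrame(0, index=index, columns=list(alignment_paths), dtype=int)
    # per (chromosome, strand): features sorted by start for bisect pruning
    by_key: dict[tuple[str, str], list[Feature]] = {}
    for f in features:
        by_key.setdefault((f.chromosome, f.strand), []).append(f)
    for key in by_key:
        by_key[key].sort(key=lambda f: f.start)
    starts = {key: [f.start for f in feats] for key, feats in by_key.items()}
    max_len = {
        key: max(f.end - f.start for f in feats) for key, feats in by_key.items()
    }
    for sample, path in alignment_paths.items():
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for read in fh:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                strand = MINUS if read.is_reverse else PLUS
                if reverse_stranded:
                    strand = MINUS if strand == PLUS else PLUS
                key = (read.reference_name, strand)
                feats = by_key.get(key)
                if not feats:
                    continue
                r_start, r_end = read.reference_start, read.reference_end
                # candidates: features starting before the read ends, whose
                # span could still reach the read start
                hi = bisect.bisect_left(starts[key], r_end)
                lo = bisect.bisect_left(starts[key], r_start - max_len[key])
                for f in feats[lo:hi]:
                    if f.start < r_end and r_start < f.end:
                        matrix.loc[f.id, sample] += 1
    return matrix


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    factor_j = median over features with all-positive counts of
    count_ij / geometric mean of feature i across samples.
    """
    counts = matrix.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ScoringError(
            "no feature has nonzero counts in every sample; "
            "add a pseudocount or drop empty samples"
        )
    kept = counts[all_positive]
    geomean = np.exp(np.log(kept).mean(axis=1, keepdims=True))
    factors = np.median(kept / geomean, axis=0)
    return pd.Series(factors, index=matrix.columns)


def log2_fold_change(
    count_a: float,
    count_b: float,
    factor_a: float,
    factor_b: float,
    pseudocount: float = 1.0,
) -> float:
    """Signed log2 ratio of size-factor-normalized counts (B over A)."""
    if factor_a <= 0 or factor_b <= 0:
        raise ScoringError("size factors must be positive")
    if pseudocount < 0:
        raise ScoringError("pseudocount must be >= 0")
    a = count_a / factor_a + pseudocount
    b = count_b / factor_b + pseudocount
    if a == 0 or b == 0:
        raise ScoringError("zero normalized count with zero pseudocount")
    return float(np.log2(b / a))


def differential_expression(
    matrix: pd.DataFrame,
    condition_of: dict[str, str],
    condition_a: str,
    condition_b: str,
    pseudocount: float = 1.0,
) -> dict[str, DEResult]:
    """Per-feature log2 fold change (B over A), averaging replicate samples
    of each condition after size-factor normalization."""
    factors = size_factors(matrix)
    samples_a = [s for s in matrix.columns if condition_of[s] == condition_a]
    samples_b = [s for s in matrix.columns if condition_of[s] == condition_b]
    if not samples_a or not samples_b:
        raise ScoringError("each condition needs at least one sample")
    norm = matrix / factors
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    results = {}
    for fid in matrix.index:
        lfc = float(np.log2((mean_b[fid] + pseudocount) / (mean_a[fid] + pseudocount)))
        results[fid] = DEResult(fid, lfc)
    return results


def mrna_raw_score(
    predictions: list[TargetPrediction],
    de: dict[str, DEResult],
    k: int = 50,
    signed_terms: bool = False,
) -> float:
    """Sum over the top-k targets of |E| x |log2fc| (or the literal signed
    product E x log2fc with ``signed_terms``); genes absent from the DE
    table contribute 0."""
    total = 0.0
    for p in predictions[:k]:
        result = de.get(p.gene_id)
        if result is None:
            continue
        if signed_terms:
            total += p.energy * result.log2fc
        else:
            total += abs(p.energy) * abs(result.log2fc)
    return total


def normalize_scores(raw: np.ndarray | list[float]) -> np.ndarray:
    """Divide by the maximum; an all-zero column stays all-zero."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw
    peak = raw.max()
    if peak <= 0:
        if raw.size:
            logger.warning("all raw scores are zero; normalized column is all zeros")
        return np.zeros_like(raw)
    return raw / peak


def combine_phenoscore(mrna_score: float, srna_score: float) -> float:
    """Sum of the two normalized components (each must be in [0, 1])."""
    for name, value in (("mrna_score", mrna_score), ("srna_score", srna_score)):
        if not 0.0 <= value <= 1.0:
            raise ScoringError(f"{name} must be in [0, 1], got {value}")
    return mrna_score + srna_score


def rank_candidates(records: list[ScoreRecord]) -> list[ScoreRecord]:
    """Order by phenoscore descending; ties by srna_score descending, then
    genomic position; assign 1-based ranks."""
    ordered = sorted(
        records,
        key=lambda r: (-r.phenoscore, -r.srna_score, r.chromosome, r.start),
    )
    for i, r in enumerate(ordered, 1):
        r.rank = i
    return ordered


def score_candidates(
    regions: list[CandidateRegion],
    targets_by_srna: dict[str, list[TargetPrediction]],
    count_matrix: pd.DataFrame,
    condition_of: dict[str, str],
    condition_a: str,
    condition_b: str,
    top_k: int = 50,
    pseudocount: float = 1.0,
    signed_mrna_terms: bool = False,
) -> list[ScoreRecord]:
    """Full scoring: differential expression of candidates and genes, raw
    components, max-normalization across candidates, phenoscore, ranking."""
    de = differential_expression(
        count_matrix, condition_of, condition_a, condition_b, pseudocount
    )
    records = []
    for region in regions:
        result = de.get(region.id)
        raw_srna = abs(result.log2fc) if result else 0.0
        raw_mrna = mrna_raw_score(
            targets_by_srna.get(region.id, []), de, top_k, signed_mrna_terms
        )
        records.append(
            ScoreRecord(
                srna_id=region.id,
                chromosome=region.chromosome,
                strand=region.strand,
                start=region.start,
                end=region.end,
                raw_srna=raw_srna,
                raw_mrna=raw_mrna,
            )
        )
    srna_norm = normalize_scores([r.raw_srna for r in records])
    mrna_norm = normalize_scores([abs(r.raw_mrna) for r in records])
    for r, s, m in zip(records, srna_norm, mrna_norm):
        r.srna_score = float(s)
        r.mrna_score = float(m)
        r.phenoscore = combine_phenoscore(r.mrna_score, r.srna_score)
    return rank_candidates(records)


def write_score_table(records: list[ScoreRecord], path) -> None:
    """Ranked TSV; 5'/3' ends are 1-based genomic coordinates oriented by
    strand (5' > 3' for minus-strand candidates)."""
    with open(path, "w") as fh:
        fh.write("sRNA\tmRNAscore\tsRNAscore\tPhenoscore\tRank\t5'-end\t3'-end\n")
        for r in records:
            if r.strand == PLUS:
                five, three = r.start + 1, r.end
            else:
                five, three = r.end, r.start + 1
            fh.write(
                f"{r.srna_id}\t{r.mrna_score:.3f}\t{r.srna_score:.3f}\t"
                f"{r.phenoscore:.3f}\t{r.rank}\t{five}\t{three}\n"
            )
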