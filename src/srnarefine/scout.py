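"""Differential intergenic peak detection and candidate-region assembly.

A candidate peak is a run of consecutive intergenic nucleotides that is
sufficiently expressed in at least one condition (>= ``min_expression`` for
>= ``min_expression_run`` nt in the positionwise max of the two averaged
tracks) and overlaps a run of sufficient differential expression
(direction-symmetric fold >= ``fold_change`` for >= ``fold_change_run`` nt).
Peaks shorter than ``min_region_length`` are expanded symmetrically about
their midpoint, and peaks within ``merge_gap`` nt of each other are merged,
yielding the candidate regions handed to target prediction and scoring.

Thresholds are in normalized (counts-per-million) units; pass raw tracks and
raw-unit thresholds together if strict raw-count replication is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import ConditionCoverage
from .genome import GenomeAnnotation, IntergenicRegion, MINUS, PLUS, intergenic_regions


class CriteriaError(ValueError):
    pass


@dataclass(frozen=True)
class FilterCriteria:
    """Peak-calling thresholds.

    The defaults are the values calibrated for the *Z. mobilis*
    aerobic/anaerobic comparison (preset ``zmobilis-aerobic``); for other
    datasets :func:`suggest_criteria` derives thresholds from the data.
    """

    min_expression: float = 34.0  # normalized coverage units
    min_expression_run: int = 24  # nt
    fold_change: float = 2.7  # ratio, >= 1
    fold_change_run: int = 15  # nt
    merge_gap: int = 50  # nt
    min_region_length: int = 200  # nt
    pseudocount: float = 1.0  # normalized coverage units, for fold ratios

    def __post_init__(self) -> None:
        if self.min_expression < 0:
            raise CriteriaError("min_expression must be >= 0")
        if self.min_expression_run < 1 or self.fold_change_run < 1:
            raise CriteriaError("run lengths must be >= 1")
        if self.fold_change < 1:
            raise CriteriaError("fold_change must be >= 1")
        if self.merge_gap < 0:
            raise CriteriaError("merge_gap must be >= 0")
        if self.min_region_length < 1:
            raise CriteriaError("min_region_length must be >= 1")
        if self.pseudocount <= 0:
            raise CriteriaError("pseudocount must be > 0")


@dataclass(frozen=True)
class CandidatePeak:
    chromosome: str
    strand: str
    start: int
    end: int
    peak_max_coverage: tuple[float, float]  # (condition A, condition B)
    peak_max_fold: float


@dataclass
class CandidateRegion:
    """A merged, length-adjusted interval proposed to contain an sRNA."""

    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    peaks: list[CandidatePeak] = field(default_factory=list)
    expanded: bool = False
    overlaps_annotation: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def find_runs(values: np.ndarray, threshold: float, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with value >= threshold and
    length >= min_len, as sorted disjoint half-open intervals."""
    if min_len < 1:
        raise CriteriaError("min_len must be >= 1")
    above = np.asarray(values) >= threshold
    if above.ndim != 1:
        raise CriteriaError("values must be 1-D")
    # run boundaries from sign changes of the padded indicator
    padded = np.concatenate(([False], above, [False]))
    diffs = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diffs == 1)
    ends = np.flatnonzero(diffs == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def fold_change_track(cov_a: np.ndarray, cov_b: np.ndarray, pseudocount: float) -> np.ndarray:
    """Direction-symmetric positionwise fold change with a pseudocount.

    fold(p) = max((a+eps)/(b+eps), (b+eps)/(a+eps)); equal coverage -> 1,
    and swapping the conditions leaves the track unchanged.
    """
    a = np.asarray(cov_a, dtype=float) + pseudocount
    b = np.asarray(cov_b, dtype=float) + pseudocount
    if a.shape != b.shape:
        raise CriteriaError("condition tracks must have equal length")
    return np.maximum(a / b, b / a)


def detect_peaks(
    cond_a: ConditionCoverage,
    cond_b: ConditionCoverage,
    igr: IntergenicRegion,
    criteria: FilterCriteria,
) -> list[CandidatePeak]:
    """Candidate peaks within one intergenic region.

    A peak is an expression run (positionwise max of the two tracks) that
    intersects at least one differential-expression run; its coordinates are
    the expression run's.
    """
    track_a = cond_a.track(igr.chromosome, igr.strand).values[igr.start : igr.end]
    track_b = cond_b.track(igr.chromosome, igr.strand).values[igr.start : igr.end]
    expr = np.maximum(track_a, track_b)
    expr_runs = find_runs(expr, criteria.min_expression, criteria.min_expression_run)
    if not expr_runs:
        return []
    fold = fold_change_track(track_a, track_b, criteria.pseudocount)
    de_runs = find_runs(fold, criteria.fold_change, criteria.fold_change_run)
    if not de_runs:
        return []
    peaks = []
    for s, e in expr_runs:
        if any(s < de and s_de < e for s_de, de in de_runs):
            peaks.append(
                CandidatePeak(
                    igr.chromosome,
                    igr.strand,
                    igr.start + s,
                    igr.start + e,
                    (float(track_a[s:e].max()), float(track_b[s:e].max())),
                    float(fold[s:e].max()),
                )
            )
    return peaks


def expand_region(
    interval: tuple[int, int], min_region_length: int, chrom_length: int
) -> tuple[int, int]:
    """Grow short intervals symmetrically about their midpoint to
    ``min_region_length``, extra nt on the higher-coordinate side when the
    deficit is odd, then clip to chromosome bounds (no re-extension)."""
    start, end = interval
    length = end - start
    if length >= min_region_length:
        return interval
    deficit = min_region_length - length
    left = deficit // 2
    right = deficit - left
    return max(0, start - left), min(chrom_length, end + right)


def merge_regions(intervals: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    """Union intervals whose gap is <= merge_gap, iterated to fixpoint.

    Output is sorted and pairwise separated by gaps strictly > merge_gap.
    """
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def scout(
    cond_a: ConditionCoverage,
    cond_b: ConditionCoverage,
    annotation: GenomeAnnotation,
    criteria: FilterCriteria | None = None,
    merge_order: str = "expand_first",
    mask_both_strands_for_structural_rna: bool = True,
) -> list[CandidateRegion]:
    """Run the full candidate search over every intergenic region of every
    strand and return id-assigned candidate regions.

    ``merge_order`` selects whether short peaks are expanded to
    ``min_region_length`` before (``expand_first``, default) or after
    (``merge_first``) nearby peaks are merged.
    """
    if criteria is None:
        criteria = FilterCriteria()
    if merge_order not in ("expand_first", "merge_first"):
        raise CriteriaError(f"invalid merge_order {merge_order!r}")
    regions: list[CandidateRegion] = []
    for strand, prefix in ((PLUS, "possRNA"), (MINUS, "negsRNA")):
        counter = 0
        for chrom in annotation.chromosomes:
            chrom_len = annotation.chromosome_length(chrom)
            peaks: list[CandidatePeak] = []
            for igr in intergenic_regions(
                annotation, strand, mask_both_strands_for_structural_rna
            ):
                if igr.chromosome != chrom:
                    continue
                peaks.extend(detect_peaks(cond_a, cond_b, igr, criteria))
            if not peaks:
                continue
            intervals = [(p.start, p.end) for p in peaks]
            if merge_order == "expand_first":
                intervals = [
                    expand_region(iv, criteria.min_region_length, chrom_len)
                    for iv in intervals
                ]
                intervals = merge_regions(intervals, criteria.merge_gap)
            else:
                intervals = merge_regions(intervals, criteria.merge_gap)
                intervals = [
                    expand_region(iv, criteria.min_region_length, chrom_len)
                    for iv in intervals
                ]
                intervals = merge_regions(intervals, criteria.merge_gap)
            for s, e in intervals:
                counter += 1
                constituents = [p for p in peaks if s < p.end and p.start < e]
                overlaps = any(
                    f.strand == strand and s < f.end and f.start < e
                    for f in annotation.features_on(chrom)
                )
                regions.append(
                    CandidateRegion(
                        id=f"{prefix}{counter}",
                        chromosome=chrom,
                        strand=strand,
                        start=s,
                        end=e,
                        peaks=constituents,
                        expanded=any(p.end - p.start < criteria.min_region_length for p in constituents),
                        overlaps_annotation=overlaps,
                    )
                )
    return regions


def suggest_criteria(
    cond_a: ConditionCoverage,
    cond_b: ConditionCoverage,
    annotation: GenomeAnnotation,
    pseudocount: float = 1.0,
    mask_both_strands_for_structural_rna: bool = True,
) -> FilterCriteria:
    """Data-derived thresholds: dataset means of intergenic expression and
    fold change over positions covered in at least one condition, with 15-nt
    run lengths."""
    expr_values: list[np.ndarray] = []
    fold_values: list[np.ndarray] = []
    for strand in (PLUS, MINUS):
        for igr in intergenic_regions(annotation, strand, mask_both_strands_for_structural_rna):
            a = cond_a.track(igr.chromosome, igr.strand).values[igr.start : igr.end]
            b = cond_b.track(igr.chromosome, igr.strand).values[igr.start : igr.end]
            support = (a > 0) | (b > 0)
            if support.any():
                expr_values.append(np.maximum(a, b)[support])
                fold_values.append(fold_change_track(a, b, pseudocount)[support])
    if not expr_values:
        raise CriteriaError("all intergenic coverage is zero; cannot derive criteria")
    all_expr = np.concatenate(expr_values)
    all_fold = np.concatenate(fold_values)
    return FilterCriteria(
        min_expression=float(all_expr.mean()),
        min_expression_run=15,
        fold_change=max(1.0, float(all_fold.mean())),
        fold_change_run=15,
        pseudocount=pseudocount,
    )


def write_candidate_bed(regions: list[CandidateRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand}\n")


def write_peak_table(regions: list[CandidateRegion], path) -> None:
    """TSV sidecar with per-region peak provenance."""
    with open(path, "w") as fh:
        fh.write(
            "region\tchromosome\tstrand\tstart\tend\tn_peaks\t"
            "max_cov_a\tmax_cov_b\tmax_fold\texpanded\toverlaps_annotation\n"
        )
        for r in regions:
            max_a = max((p.peak_max_coverage[0] for p in r.peaks), default=0.0)
            max_b = max((p.peak_max_coverage[1] for p in r.peaks), default=0.0)
            max_f = max((p.peak_max_fold for p in r.peaks), default=0.0)
            fh.write(
                f"{r.id}\t{r.chromosome}\t{r.strand}\t{r.start}\t{r.end}\t"
                f"{len(r.peaks)}\t{max_a:.4g}\t{max_b:.4g}\t{max_f:.4g}\t"
                f"{int(r.expanded)}\t{int(r.overlaps_annotation)}\n"
            )
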