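"""Strand-specific per-nucleotide read coverage: construction from
alignments, library-size normalization, replicate averaging, bedGraph I/O.

Raw coverage counts, at each position, the mapped primary reads on that
strand whose aligned reference span covers the position (CIGAR M/=/X/D
consume and are covered; N consumes but is not covered; S/I/H do not
consume).  Normalization is counts-per-million of the sample's total mapped
primary reads over both strands, so tracks from libraries of different depth
are comparable and replicates can be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeAnnotation, MINUS, PLUS, STRANDS

CPM_SCALE = 1_000_000

# CIGAR operations that consume the reference
_REF_CONSUMING_COVERED = {0, 2, 7, 8}  # M, D, =, X
_REF_CONSUMING_SKIPPED = {3}  # N


class CoverageError(ValueError):
    pass


@dataclass
class StrandedCoverage:
    """Per-nucleotide depth for one chromosome strand of one sample."""

    chromosome: str
    strand: str
    values: np.ndarray
    normalized: bool = False
    total_mapped_reads: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in STRANDS:
            raise CoverageError(f"invalid strand {self.strand!r}")
        if (self.values < 0).any():
            raise CoverageError("coverage values must be non-negative")
        if not self.normalized and not np.allclose(self.values, np.round(self.values)):
            raise CoverageError("raw coverage must be integer-valued")

    def __len__(self) -> int:
        return len(self.values)


def coverage_from_alignments(
    path,
    genome: GenomeAnnotation,
    strand: str,
    reverse_stranded: bool = False,
) -> dict[str, StrandedCoverage]:
    """Build raw coverage for ``strand`` from a SAM/BAM file, one track per
    chromosome.  ``reverse_stranded`` flips read-strand -> transcript-strand
    assignment for dUTP-style libraries.
    """
    arrays = {
        chrom: np.zeros(genome.chromosome_length(chrom), dtype=float)
        for chrom in genome.chromosomes
    }
    total = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        sq_names = set(fh.references or ())
        unknown = sq_names - set(genome.chromosomes)
        if unknown:
            raise CoverageError(
                "alignment chromosomes not in genome: "
                + ", ".join(sorted(unknown))
                + "; genome has: "
                + ", ".join(sorted(genome.chromosomes))
            )
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
            read_strand = MINUS if read.is_reverse else PLUS
            if reverse_stranded:
                read_strand = MINUS if read_strand == PLUS else PLUS
            if read_strand != strand:
                continue
            arr = arrays[read.reference_name]
            pos = read.reference_start
            for op, length in read.cigartuples or ():
                if op in _REF_CONSUMING_COVERED:
                    arr[pos : pos + length] += 1
                    pos += length
                elif op in _REF_CONSUMING_SKIPPED:
                    pos += length
    return {
        chrom: StrandedCoverage(chrom, strand, arr, normalized=False)
        for chrom, arr in arrays.items()
    }


def count_mapped_reads(path) -> int:
    """Total primary mapped alignments in a SAM/BAM file (both strands)."""
    total = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
    return total


def normalize_coverage(cov: StrandedCoverage, total_mapped_reads: int) -> StrandedCoverage:
    """Scale to counts-per-million of the sample's total mapped reads."""
    if cov.normalized:
        raise CoverageError("coverage already normalized; refusing to rescale")
    if total_mapped_reads <= 0:
        raise CoverageError("total_mapped_reads must be positive")
    return StrandedCoverage(
        cov.chromosome,
        cov.strand,
        cov.values * (CPM_SCALE / total_mapped_reads),
        normalized=True,
        total_mapped_reads=total_mapped_reads,
    )


def average_replicates(reps: list[StrandedCoverage]) -> StrandedCoverage:
    """Positionwise arithmetic mean of normalized replicate tracks."""
    if not reps:
        raise CoverageError("need at least one replicate")
    first = reps[0]
    for r in reps:
        if not r.normalized:
            raise CoverageError("all replicates must be normalized before averaging")
        if r.chromosome != first.chromosome or r.strand != first.strand:
            raise CoverageError("replicates must share chromosome and strand")
        if len(r) != len(first):
            raise CoverageError("replicate length mismatch")
    mean = np.mean([r.values for r in reps], axis=0)
    return StrandedCoverage(first.chromosome, first.strand, mean, normalized=True)


@dataclass
class ConditionCoverage:
    """All coverage for one condition: per-strand replicate tracks and their
    averages, keyed by chromosome."""

    condition: str
    averaged: dict[tuple[str, str], StrandedCoverage] = field(default_factory=dict)

    def track(self, chromosome: str, strand: str) -> StrandedCoverage:
        return self.averaged[(chromosome, strand)]

    @classmethod
    def from_replicates(
        cls, condition: str, replicates: list[dict[tuple[str, str], StrandedCoverage]]
    ) -> "ConditionCoverage":
        """Average per-(chromosome, strand) normalized replicate dicts."""
        if not replicates:
            raise CoverageError("need at least one replicate")
        keys = set(replicates[0])
        for rep in replicates:
            if set(rep) != keys:
                raise CoverageError("replicates cover different chromosome/strand sets")
        averaged = {key: average_replicates([rep[key] for rep in replicates]) for key in keys}
        return cls(condition, averaged)


def read_bedgraph(path, genome: GenomeAnnotation, strand: str, normalized: bool = True) -> dict[str, StrandedCoverage]:
    """Read a bedGraph track (0-based half-open) into per-chromosome arrays.

    Intervals must not overlap; uncovered positions are zero.
    """
    arrays = {
        chrom: np.zeros(genome.chromosome_length(chrom), dtype=float)
        for chrom in genome.chromosomes
    }
    seen = {chrom: np.zeros(genome.chromosome_length(chrom), dtype=bool) for chrom in genome.chromosomes}
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        skiprows=_bedgraph_skiprows(path),
    )
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in arrays:
            raise CoverageError(f"bedGraph chromosome {chrom!r} not in genome")
        start, end = int(row.start), int(row.end)
        if not 0 <= start < end <= len(arrays[chrom]):
            raise CoverageError(
                f"bedGraph interval [{start}, {end}) outside chromosome {chrom!r}"
            )
        if seen[chrom][start:end].any():
            raise CoverageError(f"overlapping bedGraph intervals at {chrom}:{start}-{end}")
        seen[chrom][start:end] = True
        arrays[chrom][start:end] = float(row.value)
    return {
        chrom: StrandedCoverage(chrom, strand, arr, normalized=normalized)
        for chrom, arr in arrays.items()
    }


def _bedgraph_skiprows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith(("track", "browser")) else 0


def write_bedgraph(cov: StrandedCoverage, path) -> None:
    """Write one track as bedGraph, run-length-compressing equal values and
    omitting zero runs."""
    values = cov.values
    with open(path, "w") as fh:
        start = 0
        n = len(values)
        while start < n:
            end = start + 1
            while end < n and values[end] == values[start]:
                end += 1
            if values[start] != 0:
                val = values[start]
                text = repr(int(val)) if float(val).is_integer() else repr(float(val))
                fh.write(f"{cov.chromosome}\t{start}\t{end}\t{text}\n")
            start = end
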