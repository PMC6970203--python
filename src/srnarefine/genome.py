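"""Genome sequences, stranded feature annotation, intergenic complements and
target windows.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
BED/bedGraph (0-based half-open) are converted at the I/O boundary only.

The intergenic complement is the substrate of the whole candidate search: a
position is *intergenic* on strand ``s`` when no annotated feature masks it
there.  By default rRNA/tRNA features mask both strands, because antisense
reads over structural RNA loci are overwhelmingly artifacts of library
preparation rather than evidence of independent transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

PLUS = "+"
MINUS = "-"
STRANDS = (PLUS, MINUS)

#: feature kinds that mask both strands under the default intergenic rule
STRUCTURAL_RNA_KINDS = frozenset({"rRNA", "tRNA"})

#: GFF3 types accepted as gene-like features by default
DEFAULT_FEATURE_KINDS = frozenset({"gene", "CDS", "rRNA", "tRNA", "tmRNA", "ncRNA"})

#: half-widths of the translation-start window searched for sRNA binding, nt
TARGET_WINDOW_UPSTREAM = 200
TARGET_WINDOW_DOWNSTREAM = 100


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent genome/annotation input."""


@dataclass(frozen=True)
class Feature:
    """A stranded annotated interval (gene, CDS, rRNA, tRNA, ...)."""

    id: str
    chromosome: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    kind: str = "gene"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"feature {self.id!r}: strand required (+ or -)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def masks_strand(self, strand: str, mask_both_strands_for_structural_rna: bool = True) -> bool:
        if self.strand == strand:
            return True
        return mask_both_strands_for_structural_rna and self.kind in STRUCTURAL_RNA_KINDS


@dataclass(frozen=True)
class IntergenicRegion:
    """A maximal unannotated interval on one strand."""

    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"empty intergenic region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Chromosome sequences plus stranded feature intervals."""

    chromosomes: dict[str, str] = field(default_factory=dict)  # id -> sequence
    features: list[Feature] = field(default_factory=list)

    def chromosome_length(self, chrom: str) -> int:
        try:
            return len(self.chromosomes[chrom])
        except KeyError:
            raise AnnotationError(f"unknown chromosome {chrom!r}") from None

    def sequence(self, chrom: str, start: int, end: int, strand: str = PLUS) -> str:
        seq = self.chromosomes[chrom][start:end]
        if strand == MINUS:
            seq = str(Seq(seq).reverse_complement())
        return seq

    def features_on(self, chrom: str, strand: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.chromosome == chrom and (strand is None or f.strand == strand)
        ]


def read_genome(path) -> GenomeAnnotation:
    """Read a FASTA file into a :class:`GenomeAnnotation` (sequences only)."""
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise AnnotationError(f"duplicate chromosome id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise AnnotationError(f"chromosome {record.id!r} has empty sequence")
        chromosomes[record.id] = seq
    if not chromosomes:
        raise AnnotationError(f"no sequences found in {path}")
    return GenomeAnnotation(chromosomes=chromosomes)


def read_annotation(
    path,
    genome: GenomeAnnotation,
    feature_kinds: frozenset[str] | set[str] = DEFAULT_FEATURE_KINDS,
) -> GenomeAnnotation:
    """Attach GFF3 features to a genome.

    Accepts flat (unspliced) bacterial GFF3: one feature per row, types
    filtered by ``feature_kinds``.  GFF3 1-based inclusive coordinates are
    converted to internal 0-based half-open (start-1, end).
    """
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            chrom, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype not in feature_kinds:
                continue
            if chrom not in genome.chromosomes:
                raise AnnotationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if strand not in STRANDS:
                raise AnnotationError(f"{path}:{lineno}: strand required (+ or -), got {strand!r}")
            fid = _gff_attribute(attrs, "ID") or f"{ftype}_{lineno}"
            start, end = int(start1) - 1, int(end1)
            if end > genome.chromosome_length(chrom) or start < 0:
                raise AnnotationError(
                    f"feature {fid!r} [{start1}, {end1}] exceeds bounds of {chrom!r}"
                )
            features.append(Feature(fid, chrom, start, end, strand, ftype))
    return GenomeAnnotation(chromosomes=genome.chromosomes, features=features)


def _gff_attribute(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1 :]
    return None


def write_annotation(annotation: GenomeAnnotation, path, source: str = "srnarefine") -> None:
    """Write features as GFF3 (restoring 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation.features:
            fh.write(
                "\t".join(
                    [
                        f.chromosome,
                        source,
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.id}",
                    ]
                )
                + "\n"
            )


def intergenic_regions(
    annotation: GenomeAnnotation,
    strand: str,
    mask_both_strands_for_structural_rna: bool = True,
) -> list[IntergenicRegion]:
    """Maximal intervals not covered by any masking feature on ``strand``.

    Features on the same strand always mask; rRNA/tRNA mask the opposite
    strand too unless the flag is cleared.  Regions are returned sorted by
    (chromosome, start) and are pairwise disjoint.
    """
    if strand not in STRANDS:
        raise AnnotationError(f"invalid strand {strand!r}")
    regions: list[IntergenicRegion] = []
    for chrom in annotation.chromosomes:
        length = annotation.chromosome_length(chrom)
        masks = sorted(
            (f.start, f.end)
            for f in annotation.features
            if f.chromosome == chrom
            and f.masks_strand(strand, mask_both_strands_for_structural_rna)
        )
        cursor = 0
        for start, end in masks:
            if start > cursor:
                regions.append(IntergenicRegion(chrom, strand, cursor, start))
            cursor = max(cursor, end)
        if cursor < length:
            regions.append(IntergenicRegion(chrom, strand, cursor, length))
    return regions


@dataclass(frozen=True)
class TargetWindow:
    """The translation-start-proximal sequence searched for sRNA binding."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    sequence: str  # 5'->3' in transcription orientation


def target_windows(
    annotation: GenomeAnnotation,
    upstream: int = TARGET_WINDOW_UPSTREAM,
    downstream: int = TARGET_WINDOW_DOWNSTREAM,
    gene_kinds: frozenset[str] | set[str] = frozenset({"gene", "CDS"}),
) -> list[TargetWindow]:
    """Per-gene windows from ``upstream`` nt before the translation start to
    ``downstream`` nt after it (start codon's first nt at relative offset
    ``upstream``), clipped to chromosome bounds, reverse-complemented for
    minus-strand genes.  Windows may overlap neighbouring annotation: the
    ribosome-binding-site region is of interest regardless of gene density.
    """
    windows: list[TargetWindow] = []
    for f in annotation.features:
        if f.kind not in gene_kinds:
            continue
        length = annotation.chromosome_length(f.chromosome)
        if f.strand == PLUS:
            start = max(0, f.start - upstream)
            end = min(length, f.start + downstream)
        else:
            # translation start = last nt of the interval (end - 1)
            start = max(0, f.end - downstream)
            end = min(length, f.end + upstream)
        seq = annotation.sequence(f.chromosome, start, end, f.strand)
        windows.append(TargetWindow(f.id, f.chromosome, start, end, f.strand, seq))
    return windows


def write_bed(regions, path, name_prefix: str = "IGR") -> None:
    """Write intervals as BED6 (name = <prefix>_<n>, score 0)."""
    with open(path, "w") as fh:
        for n, r in enumerate(regions, 1):
            name = getattr(r, "id", None) or f"{name_prefix}_{n}"
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
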