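"""End-to-end orchestration: coverage -> candidate search -> target
prediction -> scoring, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .config import RunConfig
from .coverage import (
    ConditionCoverage,
    count_mapped_reads,
    coverage_from_alignments,
    normalize_coverage,
)
from .genome import MINUS, PLUS, read_annotation, read_genome, target_windows
from .phenoscore import count_reads, score_candidates, write_score_table
from .scout import scout, suggest_criteria, write_candidate_bed, write_peak_table
from .targets import predict_targets_builtin, read_external_targets, write_fasta
from .genome import Feature

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _condition_coverage(
    label: str, paths: list[str], genome, reverse_stranded: bool
) -> ConditionCoverage:
    replicates = []
    for path in paths:
        total = count_mapped_reads(path)
        rep = {}
        for strand in (PLUS, MINUS):
            for chrom, cov in coverage_from_alignments(
                path, genome, strand, reverse_stranded
            ).items():
                rep[(chrom, strand)] = normalize_coverage(cov, total)
        replicates.append(rep)
    return ConditionCoverage.from_replicates(label, replicates)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_refine(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict and writes the
    candidate BED/FASTA, ranked score TSV and a run manifest to the output
    directory.  Any stage failure aborts with the stage name and cause."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "genome"
    try:
        genome = read_genome(config.genome)
        annotation = read_annotation(config.annotation, genome)

        stage = "coverage"
        cond_a = _condition_coverage(
            config.condition_a, config.alignments_a, annotation, config.reverse_stranded
        )
        cond_b = _condition_coverage(
            config.condition_b, config.alignments_b, annotation, config.reverse_stranded
        )

        stage = "scout"
        criteria = config.criteria
        if config.auto_criteria:
            criteria = suggest_criteria(
                cond_a, cond_b, annotation,
                mask_both_strands_for_structural_rna=config.mask_both_strands_for_structural_rna,
            )
        candidates = scout(
            cond_a, cond_b, annotation, criteria,
            merge_order=config.merge_order,
            mask_both_strands_for_structural_rna=config.mask_both_strands_for_structural_rna,
        )
        logger.info("scout: %d candidate regions", len(candidates))
        write_candidate_bed(candidates, out / "candidates.bed")
        write_peak_table(candidates, out / "candidates_peaks.tsv")
        srna_seqs = [
            (c.id, annotation.sequence(c.chromosome, c.start, c.end, c.strand))
            for c in candidates
        ]
        write_fasta(srna_seqs, out / "candidates.fasta")

        stage = "targets"
        windows = target_windows(annotation)
        if config.external_targets:
            predictions = read_external_targets(config.external_targets)
            targets_by_srna: dict[str, list] = {}
            for p in predictions:
                targets_by_srna.setdefault(p.srna_id, []).append(p)
            for preds in targets_by_srna.values():
                preds.sort(key=lambda p: (p.energy, p.gene_id))
                del preds[config.top_k :]
        else:
            targets_by_srna = {
                cid: predict_targets_builtin(
                    cid, seq, windows, config.hybridization, config.top_k
                )
                for cid, seq in srna_seqs
            }
        logger.info(
            "targets: %d candidates with >=1 predicted target",
            sum(1 for v in targets_by_srna.values() if v),
        )

        stage = "score"
        count_features = [
            Feature(f.id, f.chromosome, f.start, f.end, f.strand, f.kind)
            for f in annotation.features
        ] + [
            Feature(c.id, c.chromosome, c.start, c.end, c.strand, "sRNA_candidate")
            for c in candidates
        ]
        samples = {}
        condition_of = {}
        for i, path in enumerate(config.alignments_a, 1):
            name = f"{config.condition_a}_{i}"
            samples[name] = path
            condition_of[name] = config.condition_a
        for i, path in enumerate(config.alignments_b, 1):
            name = f"{config.condition_b}_{i}"
            samples[name] = path
            condition_of[name] = config.condition_b
        matrix = count_reads(samples, count_features, config.reverse_stranded)
        records = score_candidates(
            candidates, targets_by_srna, matrix, condition_of,
            config.condition_a, config.condition_b,
            top_k=config.top_k,
            pseudocount=config.count_pseudocount,
            signed_mrna_terms=config.signed_mrna_terms,
        )
        write_score_table(records, out / "phenoscores.tsv")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "config": {
            k: (v.__dict__ if hasattr(v, "__dict__") else v)
            for k, v in config.__dict__.items()
        },
        "inputs": {
            "genome": _sha256(config.genome),
            "annotation": _sha256(config.annotation),
            "alignments_a": [_sha256(p) for p in config.alignments_a],
            "alignments_b": [_sha256(p) for p in config.alignments_b],
        },
        "n_candidates": len(candidates),
        "n_scored": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "candidates": candidates,
        "records": records,
        "count_matrix": matrix,
        "criteria": criteria,
        "output_dir": str(out),
    }
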