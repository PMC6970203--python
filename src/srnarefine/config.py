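"""Run configuration: a single YAML file validated into typed objects.

CLI flags override config keys; the preset ``zmobilis-aerobic`` fills in the
filter criteria calibrated for the *Z. mobilis* aerobic/anaerobic dataset
(minimum expression 34, 24-nt run, 2.7-fold, 15-nt run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .scout import FilterCriteria
from .targets import HybridizationParams

CRITERIA_PRESETS: dict[str, FilterCriteria] = {
    "zmobilis-aerobic": FilterCriteria(
        min_expression=34.0,
        min_expression_run=24,
        fold_change=2.7,
        fold_change_run=15,
    ),
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    genome: str
    annotation: str
    condition_a: str
    condition_b: str
    alignments_a: list[str] = field(default_factory=list)  # SAM/BAM, one per replicate
    alignments_b: list[str] = field(default_factory=list)
    external_targets: str | None = None
    output_dir: str = "refine_out"
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    hybridization: HybridizationParams = field(default_factory=HybridizationParams)
    top_k: int = 50
    count_pseudocount: float = 1.0
    signed_mrna_terms: bool = False
    reverse_stranded: bool = False
    merge_order: str = "expand_first"
    mask_both_strands_for_structural_rna: bool = True
    auto_criteria: bool = False
    seed: int = 0

    def validate_paths(self) -> None:
        for key, value in (("genome", self.genome), ("annotation", self.annotation)):
            if not Path(value).exists():
                raise ConfigError(f"{key}: path does not exist: {value}")
        for key, paths in (("alignments_a", self.alignments_a), ("alignments_b", self.alignments_b)):
            if not paths:
                raise ConfigError(f"{key}: at least one alignment file required")
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"{key}: path does not exist: {p}")
        if self.external_targets and not Path(self.external_targets).exists():
            raise ConfigError(f"external_targets: path does not exist: {self.external_targets}")


def _build_criteria(raw: dict) -> FilterCriteria:
    preset = raw.pop("preset", None)
    if preset is not None and preset not in CRITERIA_PRESETS:
        raise ConfigError(f"criteria.preset: unknown preset {preset!r}")
    base = CRITERIA_PRESETS[preset] if preset else FilterCriteria()
    known = {
        "min_expression", "min_expression_run", "fold_change",
        "fold_change_run", "merge_gap", "min_region_length", "pseudocount",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"criteria: unknown keys {sorted(unknown)}")
    try:
        return FilterCriteria(**{**base.__dict__, **raw})
    except ValueError as exc:
        raise ConfigError(f"criteria: {exc}") from exc


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    criteria = _build_criteria(dict(raw.pop("criteria", {}) or {}))
    hyb_raw = dict(raw.pop("hybridization", {}) or {})
    try:
        hybridization = HybridizationParams(**{**HybridizationParams().__dict__, **hyb_raw})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"hybridization: {exc}") from exc
    required = {"genome", "annotation", "condition_a", "condition_b"}
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"missing required keys: {sorted(missing)}")
    try:
        cfg = RunConfig(criteria=criteria, hybridization=hybridization, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    if cfg.top_k < 1:
        raise ConfigError("top_k: must be >= 1")
    if cfg.count_pseudocount < 0:
        raise ConfigError("count_pseudocount: must be >= 0")
    if cfg.merge_order not in ("expand_first", "merge_first"):
        raise ConfigError(f"merge_order: invalid value {cfg.merge_order!r}")
    cfg.validate_paths()
    return cfg
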