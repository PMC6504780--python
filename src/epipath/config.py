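"""Pipeline configuration: YAML parsing, validation, canonical serialization.

Validation collects every problem (type errors, range errors, unknown
keys) and reports them together.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "serialize_config"]

_DEFAULTS = {
    "genotypes": None,
    "annotation": None,
    "gene_sets": None,
    "out_dir": "epipath_out",
    "seed": None,
    "qc": {"maf_min": 0.05, "hwe_p_min": 0.001, "max_missing": 0.05},
    "scan": {"p_screen": 1e-8, "alpha": 0.05},
    "haplotype": {"window_sizes": [2, 3, 4]},
    "gsea": {"flank": 20000, "n_perm": 1000, "min_size": 5, "max_size": 200},
}


class ConfigError(ValueError):
    """One or more configuration problems; ``errors`` lists them all."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class PipelineConfig:
    genotypes: str
    annotation: str | None = None
    gene_sets: str | None = None
    out_dir: str = "epipath_out"
    seed: int | None = None
    qc: dict = field(default_factory=lambda: dict(_DEFAULTS["qc"]))
    scan: dict = field(default_factory=lambda: dict(_DEFAULTS["scan"]))
    haplotype: dict = field(default_factory=lambda: dict(_DEFAULTS["haplotype"]))
    gsea: dict = field(default_factory=lambda: dict(_DEFAULTS["gsea"]))


def _merge_section(name: str, raw: dict, errors: list[str]) -> dict:
    merged = dict(_DEFAULTS[name])
    for key, value in raw.items():
        if key not in merged:
            errors.append(f"{name}.{key}: unknown key")
            continue
        merged[key] = value
    return merged


def validate_config(path, require_paths: bool = True) -> PipelineConfig:
    """Load and validate a YAML config; fill defaults; reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    errors: list[str] = []
    for key in raw:
        if key not in _DEFAULTS:
            errors.append(f"{key}: unknown key")
    merged = {k: raw.get(k, v) for k, v in _DEFAULTS.items() if not isinstance(v, dict)}
    for section in ("qc", "scan", "haplotype", "gsea"):
        sec_raw = raw.get(section, {})
        if not isinstance(sec_raw, dict):
            errors.append(f"{section}: must be a mapping")
            sec_raw = {}
        merged[section] = _merge_section(section, sec_raw, errors)

    if merged["genotypes"] is None:
        errors.append("genotypes: required")
    elif require_paths:
        prefix = Path(str(merged["genotypes"]))
        has_text = prefix.with_suffix(".ped").exists()
        has_bin = prefix.with_suffix(".bed").exists()
        if not (has_text or has_bin):
            errors.append(f"genotypes: no {prefix}.ped or {prefix}.bed found")
    for key in ("annotation", "gene_sets"):
        if merged[key] is not None and require_paths and not Path(merged[key]).exists():
            errors.append(f"{key}: file {merged[key]} not found")

    p_screen = merged["scan"].get("p_screen")
    if not isinstance(p_screen, (int, float)) or not 0 < p_screen < 1:
        errors.append(f"scan.p_screen: must be in (0, 1), got {p_screen!r}")
    alpha = merged["scan"].get("alpha")
    if not isinstance(alpha, (int, float)) or not 0 < alpha < 1:
        errors.append(f"scan.alpha: must be in (0, 1), got {alpha!r}")
    for k in ("maf_min", "hwe_p_min", "max_missing"):
        v = merged["qc"].get(k)
        if not isinstance(v, (int, float)) or not 0 <= v <= 1:
            errors.append(f"qc.{k}: must be in [0, 1], got {v!r}")
    sizes = merged["haplotype"].get("window_sizes")
    if (not isinstance(sizes, (list, tuple)) or not sizes
            or any(not isinstance(s, int) or not 2 <= s <= 4 for s in sizes)):
        errors.append(f"haplotype.window_sizes: must be ints in 2..4, got {sizes!r}")
    n_perm = merged["gsea"].get("n_perm")
    if not isinstance(n_perm, int) or n_perm < 0:
        errors.append(f"gsea.n_perm: must be a nonnegative integer, got {n_perm!r}")
    if isinstance(n_perm, int) and n_perm > 0 and merged["seed"] is None:
        errors.append("seed: required when gsea.n_perm > 0")
    if merged["seed"] is not None and not isinstance(merged["seed"], int):
        errors.append(f"seed: must be an integer, got {merged['seed']!r}")

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(**merged)


def serialize_config(config: PipelineConfig) -> str:
    """Canonical YAML form (sorted keys, defaults materialized)."""
    return yaml.safe_dump(asdict(config), sort_keys=True, default_flow_style=False)
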