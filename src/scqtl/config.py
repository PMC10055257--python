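"""Pipeline configuration: defaults, YAML parsing and validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PathsConfig:
    vcf: str | None = None
    mtx: str | None = None
    cells: str | None = None
    genes: str | None = None
    gwas: str | None = None
    kinship: str | None = None


@dataclass
class SimulateConfig:
    enabled: bool = False
    n_donors: int = 30
    frac_diseased: float = 0.5
    n_genes: int = 200
    snps_per_gene: int = 20
    mean_cells: float = 30.0
    n_cell_types: int = 6
    effect_size: float = 1.0
    n_global: int = 4
    n_multi: int = 4
    n_unique: int = 4
    n_sign_flip: int = 2
    n_interaction_only: int = 4


@dataclass
class IngestConfig:
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    ld_window: int = 250
    ld_step: int = 50
    ld_r2: float = 0.9
    mito_max: float = 0.20
    min_cell_frac: float = 0.10
    min_mean_count: float = 0.1
    min_cells: int = 5
    min_donors: int = 40


@dataclass
class MappingConfig:
    window: int = 1_000_000
    n_pcs: int = 20
    group_maf_min: float = 0.05
    min_donors_per_group: int = 10


@dataclass
class MashConfig:
    strong_lfsr: float = 0.1
    n_pcs: int = 5
    ed_iters: int = 50
    subset_size: int = 10_000
    subset_seed: int = 2023


@dataclass
class ClassifyConfig:
    primary: float = 0.05
    secondary: float = 0.1
    share_factor: float = 0.5
    buffer: int = 2
    prune_dist: float = 0.2


@dataclass
class ColocConfig:
    enabled: bool = True
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_eqtl: float = 0.15
    prior_sd_gwas: float = 0.2
    min_shared: int = 100
    pp4_threshold: float = 0.6
    gwas_p_cut: float = 1e-6


@dataclass
class PipelineConfig:
    """Full pipeline configuration with every stage threshold."""

    seed: int = 0
    out_dir: str = "scqtl_run"
    paths: PathsConfig = field(default_factory=PathsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    ingest: IngestConfig = field(default_factory=IngestConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    mash: MashConfig = field(default_factory=MashConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    interaction: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "paths": PathsConfig,
    "simulate": SimulateConfig,
    "ingest": IngestConfig,
    "mapping": MappingConfig,
    "mash": MashConfig,
    "classify": ClassifyConfig,
    "coloc": ColocConfig,
}

_RANGES = {
    ("classify", "primary"): (0.0, 1.0),
    ("classify", "secondary"): (0.0, 1.0),
    ("ingest", "maf_min"): (0.0, 0.5),
    ("ingest", "mito_max"): (0.0, 1.0),
    ("coloc", "pp4_threshold"): (0.0, 1.0),
}


def _coerce(cls, name: str, value):
    ftypes = {f.name: f.type for f in dataclasses.fields(cls)}
    t = ftypes[name]
    if t == "int" or t is int:
        return int(float(value))  # accepts "1e6"
    if t == "float" or t is float:
        return float(value)
    if t == "bool" or t is bool:
        if isinstance(value, str):
            return value.lower() in ("1", "true", "yes")
        return bool(value)
    return value


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and normalize a YAML pipeline config.

    Missing keys get defaults, unknown keys are rejected, numeric strings like
    "1e6" are parsed, and thresholds are range-checked.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                raw.setdefault(k, {}).update(v)
            else:
                raw[k] = v
    cfg = PipelineConfig()
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            section = getattr(cfg, key)
            known = {f.name for f in dataclasses.fields(cls)}
            if not isinstance(value, dict):
                raise ValueError(f"section '{key}' must be a mapping")
            for k2, v2 in value.items():
                if k2 not in known:
                    raise ValueError(f"unknown key '{key}.{k2}'")
                setattr(section, k2, _coerce(cls, k2, v2))
        elif key in ("seed", "out_dir", "interaction"):
            setattr(cfg, key, _coerce(PipelineConfig, key, value))
        else:
            raise ValueError(f"unknown config key '{key}'")
    for (section, name), (lo, hi) in _RANGES.items():
        v = getattr(getattr(cfg, section), name)
        if not (lo <= v <= hi):
            raise ValueError(f"{section}.{name}={v} outside [{lo}, {hi}]")
    if cfg.mapping.window <= 0:
        raise ValueError("mapping.window must be positive (in bp)")
    return cfg
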