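"""Run configuration: every threshold the pipeline applies, with the study's
printed values as defaults, plus synthetic-data generator settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    seed: int = 0

    # differential calling thresholds
    fc_up: float = 1.2
    fc_down: float = 0.83
    alpha_adj: float = 0.1
    # enrichment
    enrich_alpha: float = 0.05
    # network
    hub_log2fc_cut: float = 0.263
    top_k: int = 10
    n_permutations: int = 1000
    gcc_null: str = "uniform"  # or "degree_stratified"
    # dosimetry boundary: does exactly 1.5 mGy/y fall in HLNRA (Group II)?
    nlnra_boundary_to_hlnra: bool = True

    # synthetic quant
    n_proteins: int = 800
    de_fraction: float = 0.1
    effect_range_log2: tuple[float, float] = (0.5, 1.5)
    replicate_noise_sd: float = 0.1
    up_fraction: float = 0.5
    group_presence: float = 0.9
    # synthetic annotation
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    n_enriched: int = 5
    enrichment_odds: float = 8.0
    # synthetic interactome
    n_nodes: int = 600
    attachment_m: int = 2
    planted_module_size: int = 20
    planted_density: float = 0.8
    # synthetic qPCR
    qpcr_targets: tuple[str, ...] = tuple(f"G{i:02d}" for i in range(1, 9))
    qpcr_ref_genes: tuple[str, ...] = ("REF1", "REF2")
    qpcr_planted_log2fc: float = 1.0
    qpcr_n_per_group: int = 5
    ct_noise_sd: float = 0.2
    # synthetic dosimetry
    n_subjects: int = 40
    rate_range_uR_per_h: tuple[float, float] = (5.0, 400.0)
    occupancy_indoor: float = 0.8

    # optional externally supplied inputs (otherwise simulated)
    quant_path: str | None = None
    gmt_path: str | None = None
    interactome_paths: tuple[str, ...] = ()
    ct_path: str | None = None
    dose_path: str | None = None

    def validate(self) -> "RunConfig":
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError("need fc_down < 1 < fc_up, both positive")
        for name in ("alpha_adj", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.hub_log2fc_cut <= 0 or self.top_k <= 0:
            raise ValueError("hub_log2fc_cut and top_k must be positive")
        if self.n_permutations < 1000:
            raise ValueError("n_permutations must be ≥ 1000")
        return self

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for key, value in data.items():
            if isinstance(value, list):
                value = tuple(value)
            coerced[key] = value
        return cls(**coerced).validate()

    def with_overrides(self, overrides: dict[str, Any]) -> "RunConfig":
        data = asdict(self)
        data.update(overrides)
        return type(self).from_dict(data)
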