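"""Pipeline configuration.

A single :class:`PipelineConfig` carries every threshold the analysis uses:
the proximal/distal distance cutoffs (µm), the minimum TLS area (µm²), the
tile size for TIL scoring, the clone-overlap top-N, survival censoring
horizon, and the molecular-subtype rule parameters.  Defaults encode the
published analysis conventions; everything is overridable from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # spatial thresholds (µm / µm²)
    proximal_cutoff_um: float = 500.0
    distal_cutoff_um: float = 5000.0
    min_tls_area_um2: float = 1000.0
    tile_size_um: float = 500.0
    connectivity: int = 2  # skimage connectivity: 2 = 8-connected, 1 = 4-connected
    min_tumor_component_area_um2: float = 0.0  # no tumor-component filter by default

    # repertoire
    top_n_clones: int = 30
    clone_key: str = "cdr3_aa"  # or "cdr3_vj"

    # survival
    censor_years: float = 10.0
    age_cutoff: float = 65.0

    # expression
    ssgsea_exponent: float = 0.25
    cyt_offset: float = 0.01

    # molecular subtyping
    pole_domain_start: int = 268
    pole_domain_end: int = 471
    msi_min_frameshift_indels: int = 2
    repeat_min_copies: int = 4
    repeat_max_unit: int = 6
    cnv_high_fraction: float = 0.20  # strict >: "more than 20%"
    genome_length: int = 1_000_000  # assayed panel territory (bp), explicit denominator

    # class-code mapping for label maps (code -> semantic name)
    class_codes: dict = field(
        default_factory=lambda: {0: "background", 1: "tumor", 2: "stroma", 3: "tls"}
    )

    random_seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.proximal_cutoff_um < self.distal_cutoff_um:
            raise ConfigError(
                "require 0 < proximal_cutoff_um < distal_cutoff_um, got "
                f"{self.proximal_cutoff_um} / {self.distal_cutoff_um}"
            )
        if self.min_tls_area_um2 < 0:
            raise ConfigError("min_tls_area_um2 must be >= 0")
        if self.tile_size_um <= 0:
            raise ConfigError("tile_size_um must be > 0")
        if self.top_n_clones < 1:
            raise ConfigError("top_n_clones must be >= 1")
        if self.connectivity not in (1, 2):
            raise ConfigError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if self.clone_key not in ("cdr3_aa", "cdr3_vj"):
            raise ConfigError(f"unknown clone_key {self.clone_key!r}")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


DEFAULT_CONFIG = PipelineConfig()
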