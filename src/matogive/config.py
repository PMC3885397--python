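"""Pipeline configuration: a single YAML/JSON-style file drives a run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    fish_table: Optional[str] = None
    abundance_table: Optional[str] = None
    area_mapping: Optional[str] = None
    output_dir: str = "matogive_out"
    season_mode: int = 2
    latitude_band_edges_degS: Tuple[float, float] = (23.0, 29.0)
    length_class_width_cm: float = 5.0
    candidate_predictor_dfs: Tuple[int, ...] = (1, 2, 6)
    candidate_lat_dfs: Tuple[Optional[int], ...] = (None, 2)
    candidate_lon_dfs: Tuple[Optional[int], ...] = (None, 1)
    candidate_season_levels: Tuple[int, ...] = (2, 4)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        lo, hi = self.latitude_band_edges_degS
        if not lo < hi:
            raise ValueError(
                f"band edges must be strictly increasing, got {self.latitude_band_edges_degS}"
            )
        if self.length_class_width_cm <= 0:
            raise ValueError("length_class_width_cm must be positive")
        if self.season_mode not in (2, 4):
            raise ValueError("season_mode must be 2 or 4")

    def resolved(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in (
        "latitude_band_edges_degS",
        "candidate_predictor_dfs",
        "candidate_lat_dfs",
        "candidate_lon_dfs",
        "candidate_season_levels",
    ):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
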