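"""Reading, validating and writing the pipeline's delimited tables."""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "ValidationError",
    "read_fish_table",
    "read_abundance_table",
    "read_inputs",
    "write_table",
]


class ValidationError(ValueError):
    """Input table fails schema or row-level validation."""


def _package_version() -> str:
    try:
        return version("matogive")
    except PackageNotFoundError:
        return "unknown"


FISH_REQUIRED = ["set_id", "month", "latitude_degS", "fork_length_cm"]
# maturity may instead be derivable from histology columns
HISTOLOGY_COLUMNS = [
    "mago",
    "pofs_present",
    "alpha_atresia",
    "beta_atresia_present",
    "maturity_markers_present",
]


def read_fish_table(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate the fish table; row failures cite file line numbers."""
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in FISH_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    has_maturity = "maturity" in df.columns
    has_histology = all(c in df.columns for c in HISTOLOGY_COLUMNS)
    if not has_maturity and not has_histology:
        raise ValidationError(
            f"{path}: needs either a 'maturity' column or the histology "
            f"columns {HISTOLOGY_COLUMNS}"
        )
    problems = []
    # +2: header line plus 1-based counting
    month = pd.to_numeric(df["month"], errors="coerce")
    for idx in df.index[(month < 1) | (month > 12) | month.isna()]:
        problems.append(f"line {idx + 2}: month out of range 1-12 ({df.loc[idx, 'month']!r})")
    length = pd.to_numeric(df["fork_length_cm"], errors="coerce")
    for idx in df.index[(length <= 0) | length.isna()]:
        problems.append(
            f"line {idx + 2}: fork_length_cm must be positive "
            f"({df.loc[idx, 'fork_length_cm']!r})"
        )
    lat = pd.to_numeric(df["latitude_degS"], errors="coerce")
    for idx in df.index[lat.isna()]:
        problems.append(f"line {idx + 2}: latitude_degS missing or non-numeric")
    if problems:
        shown = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise ValidationError(f"{path}: {shown}{more}")
    return df


def read_abundance_table(
    path, area_mapping_path: Optional[str] = None, sep: str = ","
) -> pd.DataFrame:
    """Read relative abundance by area x season.

    Either columns (area, season, N) directly, or finer (cpue_area, season,
    N) plus a mapping file with columns (cpue_area, area) collapsing CPUE
    areas into the three latitudinal bands; mapped rows are summed.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    if "N" not in df.columns or "season" not in df.columns:
        raise ValidationError(f"{path}: abundance table needs columns season and N")
    if "area" not in df.columns:
        if "cpue_area" not in df.columns or area_mapping_path is None:
            raise ValidationError(
                f"{path}: needs an 'area' column, or a 'cpue_area' column "
                "plus an area-mapping file"
            )
        mapping = pd.read_csv(area_mapping_path, sep=sep, comment="#")
        if not {"cpue_area", "area"} <= set(mapping.columns):
            raise ValidationError(
                f"{area_mapping_path}: mapping needs columns cpue_area and area"
            )
        df = df.merge(mapping, on="cpue_area", how="left")
        if df["area"].isna().any():
            orphans = sorted(df.loc[df["area"].isna(), "cpue_area"].unique())
            raise ValidationError(f"unmapped cpue_area values: {orphans}")
        df = df.groupby(["area", "season"], as_index=False)["N"].sum()
    if (pd.to_numeric(df["N"], errors="coerce") < 0).any():
        raise ValidationError(f"{path}: abundance N must be non-negative")
    return df[["area", "season", "N"]]


def read_inputs(config: PipelineConfig) -> dict:
    """Read and validate all configured inputs; returns a table bundle."""
    if config.fish_table is None:
        raise ValidationError("config has no fish_table path")
    fish = read_fish_table(config.fish_table)
    bundle = {"fish": fish, "abundance": None}
    if config.abundance_table is not None:
        bundle["abundance"] = read_abundance_table(
            config.abundance_table, config.area_mapping
        )
    return bundle


def write_table(
    frame: pd.DataFrame,
    path,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a CSV with a provenance header (version, seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header_lines = [f"# matogive {_package_version()}"]
    if seed is not None:
        header_lines.append(f"# seed {seed}")
    if config is not None:
        header_lines.append(f"# config_hash {config.config_hash()}")
    with open(path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        frame.to_csv(fh, index=False, float_format="%.10g")
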