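"""Derived covariates: seasons, latitudinal bands, 5-cm length classes.

Conventions used throughout the package:

* Latitude is stored as positive degrees south (``latitude_degS``; 10 means
  10°S), so "further north" means a *smaller* value.
* Season 1 is the austral spring/summer spawning season (Oct–Mar, spanning
  the year boundary); season 2 is Apr–Sep.  The 4-level seasons are calendar
  quarters (Jan–Mar, Apr–Jun, Jul–Sep, Oct–Dec).
* Length classes are closed 5-cm intervals labelled "46-50", "51-55", ...;
  a length exactly on a boundary belongs to the lower class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BAND_EDGES_DEGS",
    "season_2level",
    "season_4level",
    "latitude_band",
    "length_class_lower",
    "length_class_midpoint",
    "length_class_label",
    "derive_covariates",
]

#: Band edges in degrees south: band 1 < 23°S, band 2 = 23–29°S, band 3 > 29°S.
DEFAULT_BAND_EDGES_DEGS = (23.0, 29.0)

_SEASON1_MONTHS = frozenset({10, 11, 12, 1, 2, 3})


def _check_months(month: np.ndarray) -> None:
    bad = (month < 1) | (month > 12) | (month != np.floor(month))
    if np.any(bad):
        first = int(np.argmax(bad))
        raise ValueError(
            f"month out of range 1-12 at position {first}: {month[first]!r}"
        )


def season_2level(month) -> np.ndarray:
    """Two seasons: 1 = Oct–Mar (spawning), 2 = Apr–Sep."""
    month = np.asarray(month)
    _check_months(month)
    return np.where((month >= 10) | (month <= 3), 1, 2)


def season_4level(month) -> np.ndarray:
    """Calendar quarters: 1 = Jan–Mar, 2 = Apr–Jun, 3 = Jul–Sep, 4 = Oct–Dec."""
    month = np.asarray(month)
    _check_months(month)
    return (month - 1) // 3 + 1


def latitude_band(latitude_degS, edges=DEFAULT_BAND_EDGES_DEGS) -> np.ndarray:
    """Discrete latitude band (1 = north of the first edge, counting south)."""
    lo, hi = edges
    if not lo < hi:
        raise ValueError(f"band edges must be strictly increasing, got {edges}")
    lat = np.asarray(latitude_degS, dtype=float)
    return np.where(lat < lo, 1, np.where(lat <= hi, 2, 3))


def length_class_lower(length_cm, width: float = 5.0) -> np.ndarray:
    """Lower bound of the closed length class containing ``length_cm``.

    Classes are (lo, lo+width] with integer-cm labels "lo+1 - lo+width";
    a fish exactly on the upper boundary stays in the lower class, so e.g.
    50.0 falls in 46-50 and 50.5 in 51-55.
    """
    length = np.asarray(length_cm, dtype=float)
    return (np.ceil(length / width) - 1) * width + 1


def length_class_midpoint(length_cm, width: float = 5.0) -> np.ndarray:
    """Midpoint of the 5-cm class, e.g. 48 for 46-50."""
    lower = length_class_lower(length_cm, width)
    return lower + (width - 1) / 2.0


def length_class_label(length_cm, width: float = 5.0) -> np.ndarray:
    lower = np.atleast_1d(length_class_lower(length_cm, width)).astype(int)
    upper = lower + int(width) - 1
    return np.array([f"{lo}-{hi}" for lo, hi in zip(lower, upper)])


def derive_covariates(
    records: pd.DataFrame,
    band_edges=DEFAULT_BAND_EDGES_DEGS,
    length_class_width_cm: float = 5.0,
) -> pd.DataFrame:
    """Attach season (2- and 4-level), latitude band and length class columns."""
    out = records.copy()
    out["season"] = season_2level(out["month"].to_numpy())
    out["quarter"] = season_4level(out["month"].to_numpy())
    out["latitude_band"] = latitude_band(
        out["latitude_degS"].to_numpy(), edges=band_edges
    )
    out["length_class_mid"] = length_class_midpoint(
        out["fork_length_cm"].to_numpy(), width=length_class_width_cm
    )
    out["length_class"] = length_class_label(
        out["fork_length_cm"].to_numpy(), width=length_class_width_cm
    )
    return out
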