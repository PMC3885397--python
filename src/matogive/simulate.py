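"""Individual-based generator for a size-structured migratory population.

The generator reproduces the statistical structure the maturity analysis
assumes, so every downstream stage can be exercised and validated without
the original samples:

* clustered sampling — fish are taken in fishing sets, each set with a
  latitude and month and a shared Gaussian set effect on the logit scale;
* a latitudinal size gradient — mean fork length decreases with degrees
  south (larger fish further north);
* a length-driven maturity process — true maturity is Bernoulli with
  logit probability ``slope * (L - L50(lat, season)) + b_set``;
* spawning migration — when enabled, mature fish in the Oct–Mar spawning
  season are displaced north before being assigned to the set that catches
  them, which makes the *apparent* proportion mature at length vary with
  latitude even when the true ogive does not;
* a length-dependent sex ratio — the proportion female declines with
  length.

Defaults emulate the sampling scale of a basin-wide albacore program: a
census of ~150 fishing sets of ~20 fish thinned to a biological sample of
~1 500 fish across 10–40°S; a true ogive with logit slope 0.2 per cm and
L50 = 87 cm at the 25°S reference latitude, decreasing towards the equator
(adults inhabit northern latitudes); and a set-effect SD of 0.5 on the
logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import (
    DEFAULT_BAND_EDGES_DEGS,
    latitude_band,
    length_class_label,
    length_class_midpoint,
    season_2level,
)

__all__ = [
    "PopulationParams",
    "simulate_population",
    "derive_abundance_inputs",
    "true_weighted_ogive",
    "true_l50",
]

#: Reference latitude (°S) at which ``L50_base_cm`` applies.
REFERENCE_LATITUDE_DEGS = 25.0


@dataclass(frozen=True)
class PopulationParams:
    """Scenario parameters for the synthetic population.

    ``true_ogive`` is (L50 at the reference latitude 25°S in cm, change in
    L50 per degree south, additive L50 shift in the Oct–Mar season, logit
    slope per cm).  ``length_by_latitude`` is (intercept cm, decrease in
    mean length per degree south, SD cm).  ``sex_ratio`` is the (intercept,
    per-cm slope) of the logit of the probability a fish is female.
    ``migration_fraction`` is the share of mature fish that undertake the
    spawning migration in a given season (the rest stay at their home
    latitude), so mature fish are still caught in the south in Oct–Mar.

    The generated frame is a census of the catchable population; a
    ``sampled`` column marks the fish entering the biological sample.
    Sampling effort is uniform except in the Oct–Mar season, where fish in
    the northern spawning zone (latitudes < ``spawning_zone_edge_degS``)
    are ``effort_bias_north_season1`` times as likely to be sampled —
    emulating a program whose spawning-season samples come mostly from the
    spawning ground, the mechanism that biases a pooled ogive low.
    ``sample_fraction`` sets the overall expected sampled share.
    """

    n_sets: int = 150
    fish_per_set_mean: float = 20.0
    latitude_range_degS: Tuple[float, float] = (10.0, 40.0)
    longitude_range_degE: Tuple[float, float] = (155.0, 230.0)
    month_weights: Tuple[float, ...] = (1.0,) * 12
    length_by_latitude: Tuple[float, float, float] = (105.0, 1.0, 6.0)
    true_ogive: Tuple[float, float, float, float] = (87.0, 0.5, 0.0, 0.2)
    set_re_sd: float = 0.5
    migration_enabled: bool = True
    migration_north_shift_degS: float = 10.0
    migration_fraction: float = 0.7
    sample_fraction: float = 0.5
    effort_bias_north_season1: float = 10.0
    spawning_zone_edge_degS: float = 23.0
    sex_ratio: Tuple[float, float] = (2.4, -0.035)
    include_ages: bool = True
    vb_growth: Tuple[float, float, float, float] = (115.0, 0.2, -1.0, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.latitude_range_degS
        if not lo < hi:
            raise ValueError(
                f"latitude range must satisfy lo < hi, got {self.latitude_range_degS}"
            )
        if self.n_sets < 1 or self.fish_per_set_mean <= 0:
            raise ValueError("need at least one set with positive mean fish count")
        if len(self.month_weights) != 12 or min(self.month_weights) < 0 or (
            sum(self.month_weights) <= 0
        ):
            raise ValueError("month_weights must be 12 non-negative reals, not all zero")
        if self.true_ogive[3] <= 0:
            raise ValueError("logit slope per cm must be positive")
        if self.set_re_sd < 0:
            raise ValueError("set_re_sd must be non-negative")
        if not 0.0 <= self.migration_fraction <= 1.0:
            raise ValueError("migration_fraction must be in [0, 1]")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.effort_bias_north_season1 <= 0:
            raise ValueError("effort_bias_north_season1 must be positive")

    def l50(self, latitude_degS, season) -> np.ndarray:
        """True L50 at a latitude and 2-level season."""
        base, lat_slope, s1_shift, _ = self.true_ogive
        lat = np.asarray(latitude_degS, dtype=float)
        season = np.asarray(season)
        return (
            base
            + lat_slope * (lat - REFERENCE_LATITUDE_DEGS)
            + s1_shift * (season == 1)
        )


def simulate_population(
    params: PopulationParams, seed: Optional[int] = None
) -> pd.DataFrame:
    """Draw one sampled population; reproducible under a fixed seed.

    Returns one row per fish in the census with observed columns (fish_id,
    set_id, month, latitude_degS, longitude_degE, fork_length_cm,
    age_years, sex, maturity 1/0), a ``sampled`` flag marking the fish in
    the biological sample (maturity models should use ``sampled`` rows;
    abundance truth uses all rows), and latent-truth columns
    (home_latitude_degS, b_set, true_l50_cm) for recovery tests.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.latitude_range_degS

    # fishing sets: month, latitude, longitude, random effect
    month_p = np.asarray(params.month_weights, dtype=float)
    month_p = month_p / month_p.sum()
    set_month = rng.choice(np.arange(1, 13), size=params.n_sets, p=month_p)
    set_lat = rng.uniform(lo, hi, size=params.n_sets)
    set_lon = rng.uniform(*params.longitude_range_degE, size=params.n_sets)
    set_b = rng.normal(0.0, params.set_re_sd, size=params.n_sets)
    n_fish = np.maximum(rng.poisson(params.fish_per_set_mean, size=params.n_sets), 1)

    home_set = np.repeat(np.arange(params.n_sets), n_fish)
    n = home_set.size
    home_lat = set_lat[home_set]
    month = set_month[home_set]
    season = season_2level(month)

    intercept, lat_slope, sd = params.length_by_latitude
    length = rng.normal(intercept - lat_slope * home_lat, sd)
    length = np.clip(length, 30.0, None)

    slope = params.true_ogive[3]
    l50 = params.l50(home_lat, season)
    eta = slope * (length - l50) + set_b[home_set]
    mature = rng.random(n) < expit(eta)

    # spawning migration: mature fish in Oct-Mar are displaced north and
    # caught by the season-1 set nearest their displaced latitude
    catch_set = home_set.copy()
    if params.migration_enabled and params.migration_north_shift_degS != 0.0:
        movers = mature & (season == 1) & (rng.random(n) < params.migration_fraction)
        if np.any(movers):
            # displaced latitude, with dispersion so migrants spread over
            # many sets instead of aggregating in the single nearest one
            target = np.clip(
                home_lat[movers]
                - params.migration_north_shift_degS
                + rng.normal(0.0, 1.5, movers.sum()),
                lo,
                hi,
            )
            s1_sets = np.flatnonzero(np.isin(set_month, (10, 11, 12, 1, 2, 3)))
            if s1_sets.size:
                order = np.argsort(set_lat[s1_sets])
                s1_sorted = s1_sets[order]
                s1_lats = set_lat[s1_sorted]
                lo_idx = np.searchsorted(s1_lats, target - 2.5, side="left")
                hi_idx = np.searchsorted(s1_lats, target + 2.5, side="right")
                # empty windows fall back to the nearest season-1 set
                nearest = np.clip(
                    np.searchsorted(s1_lats, target), 0, s1_lats.size - 1
                )
                width = hi_idx - lo_idx
                pick = np.where(
                    width > 0,
                    lo_idx + (rng.random(target.size) * np.maximum(width, 1)).astype(int),
                    nearest,
                )
                catch_set[movers] = s1_sorted[np.clip(pick, 0, s1_lats.size - 1)]

    lat_obs = set_lat[catch_set]
    lon_obs = set_lon[catch_set]
    month_obs = set_month[catch_set]

    sr_int, sr_slope = params.sex_ratio
    female = rng.random(n) < expit(sr_int + sr_slope * length)

    # effort thinning at the set level: sampling happens where the fleet
    # fishes, and in Oct-Mar the fleet concentrates on the spawning ground
    # the fleet concentrates on the spawning ground only when aggregations
    # form there, i.e. when migration is active
    set_season = season_2level(set_month)
    effort_bias = (
        params.effort_bias_north_season1 if params.migration_enabled else 1.0
    )
    set_effort = np.where(
        (set_season == 1) & (set_lat < params.spawning_zone_edge_degS),
        effort_bias,
        1.0,
    )
    # normalise within season so the spawning-season concentration does not
    # starve the Apr-Sep sample
    p_keep = np.empty(params.n_sets)
    for s in (1, 2):
        sel = set_season == s
        if np.any(sel):
            p_keep[sel] = params.sample_fraction * set_effort[sel] / set_effort[sel].mean()
    p_keep = np.clip(p_keep, 0.0, 1.0)
    set_kept = rng.random(params.n_sets) < p_keep
    sampled = set_kept[catch_set]

    if params.include_ages:
        linf, k, t0, cv = params.vb_growth
        frac = np.clip(length / linf, None, 0.98)
        age = t0 - np.log(1.0 - frac) / k
        age = np.clip(age * rng.lognormal(0.0, cv, size=n), 0.5, None)
    else:
        age = np.full(n, np.nan)

    return pd.DataFrame(
        {
            "fish_id": np.arange(n),
            "set_id": catch_set,
            "month": month_obs,
            "latitude_degS": lat_obs,
            "longitude_degE": lon_obs,
            "fork_length_cm": length,
            "age_years": age,
            "sex": np.where(female, "F", "M"),
            "maturity": mature.astype(int),
            "sampled": sampled,
            "home_latitude_degS": home_lat,
            "b_set": set_b[home_set],
            "true_l50_cm": l50,
        }
    )


def derive_abundance_inputs(
    population: pd.DataFrame,
    band_edges=DEFAULT_BAND_EDGES_DEGS,
    length_class_width_cm: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate a population into the weighting inputs.

    Returns ``(N, p, f)``: fish counts (both sexes) per area x season; the
    within-(area, season) length-class composition, summing to 1; and the
    proportion female per (length class, area, season).  Cells never
    sampled carry ``p = 0`` and ``f = NaN`` (an explicit missing marker).
    """
    if population.empty:
        raise ValueError("population is empty")
    df = population.copy()
    df["area"] = latitude_band(df["latitude_degS"].to_numpy(), edges=band_edges)
    df["season"] = season_2level(df["month"].to_numpy())
    df["length_class_mid"] = length_class_midpoint(
        df["fork_length_cm"].to_numpy(), width=length_class_width_cm
    )

    N = (
        df.groupby(["area", "season"], as_index=False)
        .size()
        .rename(columns={"size": "N"})
    )

    classes = np.sort(df["length_class_mid"].unique())
    areas = np.sort(df["area"].unique())
    seasons = np.sort(df["season"].unique())
    grid = pd.MultiIndex.from_product(
        [classes, areas, seasons], names=["length_class_mid", "area", "season"]
    ).to_frame(index=False)

    counts = (
        df.groupby(["length_class_mid", "area", "season"], as_index=False)
        .agg(n=("fish_id", "size"), n_female=("sex", lambda s: int((s == "F").sum())))
    )
    tab = grid.merge(counts, how="left", on=["length_class_mid", "area", "season"])
    tab["n"] = tab["n"].fillna(0).astype(int)
    tab["n_female"] = tab["n_female"].fillna(0).astype(int)
    totals = tab.groupby(["area", "season"])["n"].transform("sum")
    tab["p"] = np.where(totals > 0, tab["n"] / totals, np.nan)
    tab["f"] = np.where(tab["n"] > 0, tab["n_female"] / tab["n"].replace(0, 1), np.nan)

    p = tab[["length_class_mid", "area", "season", "p"]].copy()
    f = tab[["length_class_mid", "area", "season", "f"]].copy()
    return N, p, f


def _gauss_hermite_expit(eta: np.ndarray, sigma: float, n_nodes: int = 31) -> np.ndarray:
    """E[expit(eta + b)] for b ~ N(0, sigma^2), by Gauss-Hermite."""
    if sigma <= 0:
        return expit(eta)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    w = weights / np.sqrt(np.pi)
    return expit(eta[..., None] + np.sqrt(2.0) * sigma * nodes) @ w


def true_weighted_ogive(
    params: PopulationParams,
    lengths: Sequence[float],
    season: int = 2,
    n_lat: int = 201,
    n_nodes: int = 31,
) -> np.ndarray:
    """Exact population proportion mature at length, by numerical integration.

    Marginalises over latitude — weighting each latitude by the density of
    fish of that length there (set latitudes are uniform; length is Gaussian
    around the latitudinal gradient) — and over the set effect by
    Gauss-Hermite quadrature.  Migration does not enter: moving fish does
    not change the population's maturity at length.
    """
    lengths = np.asarray(lengths, dtype=float)
    lo, hi = params.latitude_range_degS
    lat = np.linspace(lo, hi, n_lat)
    intercept, lat_slope, sd = params.length_by_latitude
    mu = intercept - lat_slope * lat

    # p(lat | L) on the grid, for each length
    dens = np.exp(-0.5 * ((lengths[:, None] - mu[None, :]) / sd) ** 2)
    dens_sum = dens.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        w_lat = np.where(dens_sum > 0, dens / dens_sum, 1.0 / n_lat)

    slope = params.true_ogive[3]
    l50 = params.l50(lat, season)  # (n_lat,)
    eta = slope * (lengths[:, None] - l50[None, :])
    p_cond = _gauss_hermite_expit(eta, params.set_re_sd, n_nodes)  # (nL, n_lat)
    return np.sum(w_lat * p_cond, axis=1)


def true_l50(params: PopulationParams, season: int = 2) -> float:
    """Length at which the true population ogive crosses 0.5."""
    from scipy.optimize import brentq

    def f(L):
        return float(true_weighted_ogive(params, [L], season=season)[0]) - 0.5

    lo, hi = 40.0, 130.0
    return float(brentq(f, lo, hi, xtol=1e-4))
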