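"""Abundance-weighted population maturity ogive with variance.

A single maturity curve estimated by pooling samples across space and time
is biased whenever sampling effort is not proportional to abundance — for
a migratory stock, spawning-ground samples over-represent mature fish.
The estimator here combines area-specific model predictions with relative
abundance: for 5-cm length class ``l``, latitudinal area ``a`` and season
``s``,

    P_ls     = sum_a W_las * p_las
    W_las    = N_as * p(len)_las * f_las / sum_a' (...)
    Var(P_ls) = sum_a W_las^2 * Var(p_las)        (weights treated as known)

where ``p_las`` is the model-predicted proportion mature, ``N_as`` the
relative abundance of fish (both sexes, e.g. from standardised CPUE),
``p(len)_las`` the length composition and ``f_las`` the proportion female.
The reduced variance formula ignores uncertainty in the weights, so the
reported intervals are flagged as underestimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariates import DEFAULT_BAND_EDGES_DEGS, latitude_band, season_2level
from .glmm import GLMMFit, ModelSpec, fit_logistic_glmm, fit_model, predict_proportion

__all__ = [
    "OgiveEstimate",
    "UnweightedOgive",
    "area_season_ogives",
    "compute_weights",
    "combine_weighted",
    "fit_unweighted",
    "length_at_quantile",
]

logger = logging.getLogger(__name__)

#: Discrete-latitude refit used for area-specific predictions: length spline
#: 2 df, 3 latitude bands, 2 seasons, latitude x season interaction, set RE.
DISCRETE_LATITUDE_SPEC = ModelSpec(
    predictor="length",
    predictor_df=2,
    lat_term="discrete3",
    season_levels=2,
    lat_season_interaction=True,
)


@dataclass
class OgiveEstimate:
    """Weighted population ogive per season, plus the per-area inputs.

    ``by_length``: columns (length_class_mid, season, estimate, variance,
    ci_low, ci_high).  ``by_area``: long format with the area-specific
    predictions and weights.  ``ci_note`` records that the intervals omit
    weight uncertainty.
    """

    by_length: pd.DataFrame
    by_area: pd.DataFrame
    ci_note: str = (
        "CIs underestimate uncertainty: abundance, length-composition and "
        "sex-ratio weights are treated as known"
    )


def _band_representative_latitudes(edges=DEFAULT_BAND_EDGES_DEGS) -> dict:
    lo, hi = edges
    return {1: lo - 3.0, 2: (lo + hi) / 2.0, 3: hi + 3.0}


def area_season_ogives(
    records: pd.DataFrame,
    length_grid: Optional[Sequence[float]] = None,
    band_edges=DEFAULT_BAND_EDGES_DEGS,
    length_class_width_cm: float = 5.0,
    spec: Optional[ModelSpec] = None,
) -> tuple[pd.DataFrame, GLMMFit]:
    """Fit the discrete-latitude model and predict per area and season.

    ``records`` are female fish with maturity calls.  Predictions (with
    variance on the proportion scale via the delta method) are made at the
    5-cm class midpoints spanning the observed lengths, for every
    area x season cell.  Requires data in all three bands and both seasons.
    """
    df = records.copy()
    df["_area"] = latitude_band(df["latitude_degS"].to_numpy(), edges=band_edges)
    df["_season"] = season_2level(df["month"].to_numpy())
    for a in (1, 2, 3):
        for s in (1, 2):
            if not ((df["_area"] == a) & (df["_season"] == s)).any():
                raise ValueError(
                    f"no records in latitude band {a}, season {s}; "
                    "the discrete-latitude model needs every stratum occupied"
                )

    if spec is None:
        spec = ModelSpec(
            predictor="length",
            predictor_df=2,
            lat_term="discrete3",
            season_levels=2,
            lat_season_interaction=True,
            band_edges=tuple(band_edges),
        )
    fit = fit_model(records, spec)

    if length_grid is None:
        w = length_class_width_cm
        lengths = df["fork_length_cm"].to_numpy()
        first = (np.ceil(lengths.min() / w) - 1) * w + 1 + (w - 1) / 2.0
        last = (np.ceil(lengths.max() / w) - 1) * w + 1 + (w - 1) / 2.0
        length_grid = np.arange(first, last + w / 2.0, w)
    length_grid = np.asarray(length_grid, dtype=float)

    rep_lat = _band_representative_latitudes(band_edges)
    out = []
    for a in (1, 2, 3):
        for s in (1, 2):
            newdata = pd.DataFrame(
                {
                    "fork_length_cm": length_grid,
                    "latitude_degS": rep_lat[a],
                    "month": 12 if s == 1 else 6,
                }
            )
            pred = predict_proportion(fit, newdata)
            p = pred["proportion"].to_numpy()
            var_logit = pred["se_logit"].to_numpy() ** 2
            var_p = (p * (1.0 - p)) ** 2 * var_logit  # delta method
            out.append(
                pd.DataFrame(
                    {
                        "length_class_mid": length_grid,
                        "area": a,
                        "season": s,
                        "p_hat": p,
                        "var_p": var_p,
                        "ci_low": pred["ci_low"].to_numpy(),
                        "ci_high": pred["ci_high"].to_numpy(),
                    }
                )
            )
    return pd.concat(out, ignore_index=True), fit


def compute_weights(
    N: pd.DataFrame, p: pd.DataFrame, f: pd.DataFrame
) -> pd.DataFrame:
    """Female-abundance weights W_las = N_as p_las f_las, normalised over areas.

    Inputs are long-format frames: ``N`` with (area, season, N), ``p`` with
    (length_class_mid, area, season, p), ``f`` likewise with ``f``.  Cells
    missing in all areas stay undefined (NaN); cells missing in some areas
    have weights renormalised over the remaining areas, with a logged note.
    """
    for name, frame, cols in (
        ("N", N, ["area", "season", "N"]),
        ("p", p, ["length_class_mid", "area", "season", "p"]),
        ("f", f, ["length_class_mid", "area", "season", "f"]),
    ):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"{name} table missing columns {missing}")
    if (N["N"] < 0).any() or (p["p"].dropna() < 0).any() or (
        (f["f"].dropna() < 0) | (f["f"].dropna() > 1)
    ).any():
        raise ValueError("abundance/composition inputs must be non-negative (f in [0,1])")
    for s, grp in N.groupby("season"):
        if not (grp["N"] > 0).any():
            raise ValueError(f"abundance table has no positive entry in season {s}")

    tab = p.merge(f, on=["length_class_mid", "area", "season"], how="outer")
    tab = tab.merge(N[["area", "season", "N"]], on=["area", "season"], how="left")
    tab["raw"] = tab["N"] * tab["p"] * tab["f"]
    denom = tab.groupby(["length_class_mid", "season"])["raw"].transform(
        lambda v: v.sum(min_count=1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        tab["W"] = np.where(denom > 0, tab["raw"] / denom, np.nan)
    dropped = tab["raw"].isna() & denom.notna() & (denom > 0)
    if dropped.any():
        logger.info(
            "%d (length, area, season) cells had no composition data; "
            "weights renormalised over the remaining areas",
            int(dropped.sum()),
        )
    return tab[["length_class_mid", "area", "season", "W"]]


def combine_weighted(
    area_ogives: pd.DataFrame,
    weights: pd.DataFrame,
    level: float = 0.95,
) -> OgiveEstimate:
    """Weighted average of area-specific ogives with the reduced variance.

    ``area_ogives`` needs (length_class_mid, area, season, p_hat, var_p);
    ``weights`` needs (length_class_mid, area, season, W).  Length classes
    with no defined weight in any area are omitted.
    """
    tab = area_ogives.merge(
        weights, on=["length_class_mid", "area", "season"], how="left"
    )
    pos = tab["W"].fillna(0.0) > 0
    if (pos & tab["var_p"].isna()).any():
        bad = tab.loc[pos & tab["var_p"].isna()].iloc[0]
        raise ValueError(
            "missing variance where the weight is positive: "
            f"length {bad['length_class_mid']}, area {bad['area']}, "
            f"season {bad['season']}"
        )
    tab = tab[tab["W"].notna()].copy()

    def agg(grp: pd.DataFrame) -> pd.Series:
        w = grp["W"].to_numpy()
        est = float(np.sum(w * grp["p_hat"].to_numpy()))
        var = float(np.sum(w**2 * grp["var_p"].to_numpy()))
        return pd.Series({"estimate": est, "variance": var})

    by_length = (
        tab.groupby(["length_class_mid", "season"])
        .apply(agg, include_groups=False)
        .reset_index()
    )
    z = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(by_length["variance"].to_numpy())
    by_length["ci_low"] = np.clip(by_length["estimate"] - z * se, 0.0, 1.0)
    by_length["ci_high"] = np.clip(by_length["estimate"] + z * se, 0.0, 1.0)
    return OgiveEstimate(by_length=by_length, by_area=tab)


@dataclass
class UnweightedOgive:
    """Season-specific logistic ogive ignoring latitude (set RE retained)."""

    season: int
    fit: GLMMFit
    length_center: float

    @property
    def l50(self) -> float:
        b0, b1 = self.fit.beta
        return self.length_center - b0 / b1

    def l50_ci(self, level: float = 0.95) -> tuple[float, float]:
        # delta method on L50 = c - b0/b1
        b0, b1 = self.fit.beta
        g = np.array([-1.0 / b1, b0 / b1**2])
        var = float(g @ self.fit.cov_beta @ g)
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        return self.l50 - half, self.l50 + half

    def predict(self, lengths: Sequence[float]) -> np.ndarray:
        from scipy.special import expit

        lengths = np.asarray(lengths, dtype=float)
        b0, b1 = self.fit.beta
        return expit(b0 + b1 * (lengths - self.length_center))


def fit_unweighted(records: pd.DataFrame, season: int) -> UnweightedOgive:
    """Plain logistic ogive for one season, pooling across latitudes.

    Maturity on (centered) length with the fishing-set random intercept
    retained; no spatial covariates.  The customary single-curve estimate
    whose bias the weighted estimator corrects.
    """
    df = records.copy()
    df["_season"] = season_2level(df["month"].to_numpy())
    sub = df[df["_season"] == season]
    if sub.empty:
        raise ValueError(f"no records in season {season}")
    y = sub["maturity"].to_numpy(dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError(f"season {season} lacks both maturity states")
    L = sub["fork_length_cm"].to_numpy(dtype=float)
    center = float(L.mean())
    X = np.column_stack([np.ones_like(L), L - center])
    fit = fit_logistic_glmm(
        X, y, sub["set_id"].to_numpy(), column_names=["intercept", "length"]
    )
    return UnweightedOgive(season=season, fit=fit, length_center=center)


def length_at_quantile(
    ogive: OgiveEstimate | pd.DataFrame,
    q: float,
    season: int,
    full_maturity_threshold: float = 0.99,
) -> float:
    """Length at which the weighted ogive reaches proportion ``q``.

    For ``q < 1``: linear interpolation between the bracketing class
    midpoints of the first upward crossing.  For ``q = 1``: the smallest
    class midpoint whose estimate reaches ``full_maturity_threshold``
    (curves approach 1 only asymptotically).  NaN when the grid never
    reaches the target.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    frame = ogive.by_length if isinstance(ogive, OgiveEstimate) else ogive
    sub = frame[frame["season"] == season].sort_values("length_class_mid")
    if sub.empty:
        raise ValueError(f"ogive has no season {season}")
    L = sub["length_class_mid"].to_numpy(dtype=float)
    P = sub["estimate"].to_numpy(dtype=float)
    if q == 1.0:
        hit = np.flatnonzero(P >= full_maturity_threshold)
        return float(L[hit[0]]) if hit.size else np.nan
    for i in range(len(L)):
        if P[i] >= q:
            if i == 0:
                return float(L[0])
            frac = (q - P[i - 1]) / (P[i] - P[i - 1])
            return float(L[i - 1] + frac * (L[i] - L[i - 1]))
    return np.nan
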