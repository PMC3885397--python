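"""AICc multi-model inference over candidate maturity models.

Candidate models differ in the flexibility of the length/age spline, the
presence and form of latitude and longitude terms, the number of season
levels, and interactions.  Models are ranked by the small-sample corrected
Akaike criterion

    AICc = -2 log L + 2k + 2k(k+1)/(n - k - 1),

with k counting fixed effects plus one for the random-intercept variance
and n the number of fish.  Akaike weights w_i = exp(-Delta_i/2) normalised
over the candidate set quantify the relative evidence for each model.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .glmm import (
    ConvergenceWarning,
    GLMMFit,
    ModelSpec,
    fit_model,
    predict_proportion,
)

__all__ = [
    "ComparisonRow",
    "aicc",
    "akaike_weights",
    "candidate_grid",
    "compare_models",
    "comparison_table",
    "head_to_head",
    "l50_by_latitude",
    "l50_from_curve",
]

logger = logging.getLogger(__name__)


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC; undefined when n_obs <= n_params + 1."""
    k, n = n_params, n_obs
    if n <= k + 2:
        raise ValueError(
            f"AICc undefined at or below the boundary n_obs={n}, n_params={k}: "
            "the small-sample correction needs n_obs > n_params + 2"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Normalised evidence weights exp(-Delta/2) / sum(exp(-Delta/2))."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or np.any(~np.isfinite(a)):
        raise ValueError("aicc values must be a non-empty finite vector")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ComparisonRow:
    model_id: str
    spec: Optional[ModelSpec]
    aicc: float
    delta_aicc: float = np.nan
    akaike_weight: float = np.nan
    fit: Optional[GLMMFit] = None


def candidate_grid(
    predictor: str = "length",
    predictor_dfs: Sequence[int] = (1, 2, 6),
    lat_dfs: Sequence[Optional[int]] = (None, 2),
    lon_dfs: Sequence[Optional[int]] = (None, 1),
    season_levels: Sequence[int] = (2, 4),
    interactions: Sequence[bool] = (False, True),
) -> list[ModelSpec]:
    """Enumerate the candidate-model grid along the configured axes.

    Interactions are only attached to models containing the corresponding
    main effect, so the grid contains no redundant specs.
    """
    specs = []
    seen = set()
    for pdf, ldf, odf, ssn, lat_x, lon_x in itertools.product(
        predictor_dfs, lat_dfs, lon_dfs, season_levels, interactions, interactions
    ):
        if lat_x and ldf is None:
            continue
        if lon_x and odf is None:
            continue
        spec = ModelSpec(
            predictor=predictor,
            predictor_df=pdf,
            lat_term=None if ldf is None else "spline",
            lat_df=ldf if ldf is not None else 2,
            lon_df=odf,
            season_levels=ssn,
            lat_season_interaction=lat_x,
            lon_season_interaction=lon_x,
        )
        key = spec.model_id()
        if key not in seen:
            seen.add(key)
            specs.append(spec)
    return specs


def compare_models(
    records: pd.DataFrame,
    candidate_specs: Sequence[ModelSpec],
    keep_fits: bool = False,
) -> list[ComparisonRow]:
    """Fit every candidate and rank by AICc with Akaike weights.

    Non-converged fits are excluded with a logged warning; if every fit
    fails an error is raised.
    """
    rows = []
    for spec in candidate_specs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                fit = fit_model(records, spec)
        except Exception as exc:  # noqa: BLE001 - each failure is reported
            logger.warning("candidate %s excluded: %s", spec.model_id(), exc)
            continue
        rows.append(
            ComparisonRow(
                model_id=spec.model_id(),
                spec=spec,
                aicc=aicc(fit.loglik, fit.n_params, fit.n_obs),
                fit=fit if keep_fits else None,
            )
        )
    if not rows:
        raise RuntimeError("all candidate model fits failed")
    values = [r.aicc for r in rows]
    weights = akaike_weights(values)
    best = min(values)
    for row, w in zip(rows, weights):
        row.delta_aicc = row.aicc - best
        row.akaike_weight = float(w)
    rows.sort(key=lambda r: r.aicc)
    return rows


def comparison_table(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a frame mirroring the published table layout."""
    recs = []
    for i, r in enumerate(rows, start=1):
        s = r.spec
        recs.append(
            {
                "model": i,
                "model_id": r.model_id,
                "pred_df": s.predictor_df if s else np.nan,
                "lat_df": (
                    "D3" if (s and s.lat_term == "discrete3")
                    else (s.lat_df if (s and s.lat_term == "spline") else "")
                ),
                "lon_df": s.lon_df if (s and s.lon_df is not None) else "",
                "ssn": s.season_levels if s else np.nan,
                "lat_x_ssn": "Y" if (s and s.lat_season_interaction) else "",
                "lon_x_ssn": "Y" if (s and s.lon_season_interaction) else "",
                "aicc": r.aicc,
                "delta_aicc": r.delta_aicc,
                "weight": r.akaike_weight,
            }
        )
    return pd.DataFrame(recs)


def head_to_head(
    records_with_age: pd.DataFrame,
    predictor_df: int = 6,
    lat_df: int = 2,
    season_levels: int = 4,
) -> list[ComparisonRow]:
    """Length vs age as maturity predictors on the identical aged subset.

    Fits the same structure (spline predictor, latitude spline, season
    factor, latitude x season interaction, set random intercept) once with
    length and once with age, and reports the pairwise AICc comparison.
    """
    if "age_years" not in records_with_age.columns:
        raise ValueError("records lack an age_years column")
    aged = records_with_age
    if aged["age_years"].isna().any():
        raise ValueError(
            "every record must have an age for the length-vs-age comparison; "
            "subset to aged fish first"
        )
    rows = []
    for predictor in ("age", "length"):
        spec = ModelSpec(
            predictor=predictor,
            predictor_df=predictor_df,
            lat_term="spline",
            lat_df=lat_df,
            season_levels=season_levels,
            lat_season_interaction=True,
        )
        fit = fit_model(aged, spec)
        rows.append(
            ComparisonRow(
                model_id=spec.model_id(),
                spec=spec,
                aicc=aicc(fit.loglik, fit.n_params, fit.n_obs),
            )
        )
    weights = akaike_weights([r.aicc for r in rows])
    best = min(r.aicc for r in rows)
    for row, w in zip(rows, weights):
        row.delta_aicc = row.aicc - best
        row.akaike_weight = float(w)
    rows.sort(key=lambda r: r.aicc)
    return rows


def _crossing(
    lengths: np.ndarray, values: np.ndarray, fit_predict, target: float = 0.5,
    tol: float = 0.01,
) -> float:
    """Smallest length where the curve crosses ``target`` from below,
    refined by bisection to ``tol`` cm.  NaN when there is no crossing."""
    below = values < target
    above = values >= target
    idx = None
    for i in range(len(lengths) - 1):
        if below[i] and above[i + 1]:
            idx = i
            break
    if idx is None:
        if above[0]:
            return np.nan  # already above target at the smallest length
        return np.nan
    try:
        return float(
            optimize.brentq(
                lambda L: fit_predict(L) - target,
                lengths[idx],
                lengths[idx + 1],
                xtol=tol,
            )
        )
    except ValueError:
        return np.nan


def l50_from_curve(lengths: np.ndarray, proportions: np.ndarray) -> float:
    """First upward 0.5-crossing by linear interpolation on a tabulated curve."""
    lengths = np.asarray(lengths, dtype=float)
    proportions = np.asarray(proportions, dtype=float)

    def interp(L):
        return np.interp(L, lengths, proportions)

    return _crossing(lengths, proportions, interp)


def l50_by_latitude(
    fit: GLMMFit,
    latitudes: Sequence[float],
    season: int,
    level: float = 0.95,
    n_grid: int = 256,
    longitude: Optional[float] = None,
) -> pd.DataFrame:
    """Length at 50% maturity (with CI) as a function of latitude.

    For each latitude, predicts the maturity curve over the training length
    span and locates the first upward 0.5 crossing (root-found to 0.01 cm);
    CI bounds are the crossings of the upper/lower 95% prediction bands
    (the upper band crosses 0.5 at a shorter length, so it yields the lower
    confidence limit for L50).  Latitudes whose curve never crosses 0.5 get
    missing values.
    """
    if fit.design_info is None or fit.spec is None:
        raise ValueError("fit carries no design info; build it via fit_model")
    if fit.spec.predictor != "length":
        raise ValueError("L50 requires a length-based model")
    basis = fit.design_info.bases["length"]
    lo, hi = basis.train_min, basis.train_max
    grid = np.linspace(lo, hi, n_grid)
    month = 12 if season == 1 else 6  # representative month per season

    out = []
    for lat in latitudes:
        newdata = pd.DataFrame(
            {"fork_length_cm": grid, "latitude_degS": lat, "month": month}
        )
        if longitude is not None:
            newdata["longitude_degE"] = longitude
        elif "longitude" in fit.design_info.bases:
            newdata["longitude_degE"] = np.mean(
                [fit.design_info.bases["longitude"].train_min,
                 fit.design_info.bases["longitude"].train_max]
            )
        pred = predict_proportion(fit, newdata, level=level)
        if not np.all(np.isfinite(pred["proportion"])):
            raise ValueError(f"non-finite predictions at latitude {lat}")

        def curve_fn(col):
            vals = pred[col].to_numpy()

            def f(L):
                return np.interp(L, grid, vals)

            return vals, f

        p_vals, p_fn = curve_fn("proportion")
        hi_vals, hi_fn = curve_fn("ci_high")
        lo_vals, lo_fn = curve_fn("ci_low")
        l50 = _crossing(grid, p_vals, p_fn)
        ci_low = _crossing(grid, hi_vals, hi_fn)   # upper band -> lower L50 bound
        ci_high = _crossing(grid, lo_vals, lo_fn)  # lower band -> upper L50 bound
        out.append(
            {
                "latitude_degS": lat,
                "season": season,
                "L50": l50,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "reason": "" if np.isfinite(l50) else "no 0.5 crossing in length span",
            }
        )
    return pd.DataFrame(out)
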