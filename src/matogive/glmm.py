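"""Binomial logit mixed models with a fishing-set random intercept.

Maturity (1 = mature) is modelled on the logit scale as a function of a
length or age spline, optional latitude and longitude terms, a season
factor and optional latitude x season / longitude x season interactions,
with a Gaussian random intercept shared by fish from the same fishing set
(fish caught together are not independent).

Estimation maximises the Laplace-approximate marginal likelihood over the
fixed effects and the random-intercept standard deviation.  The per-set
conditional modes are found by damped Newton iterations, vectorised across
sets; the outer optimisation uses L-BFGS-B with the standard deviation
bounded at zero, so the fit collapses cleanly to plain logistic regression
when the between-set variance is not supported by the data.  An adaptive
Gauss-Hermite quadrature evaluator of the same marginal likelihood is
provided as an independent numerical check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

from .covariates import (
    DEFAULT_BAND_EDGES_DEGS,
    latitude_band,
    season_2level,
    season_4level,
)
from .splines import SplineBasis, SplineSpec, spline_basis

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "DesignMatrices",
    "GLMMFit",
    "SeparationError",
    "ConvergenceWarning",
    "build_design",
    "fit_logistic_glmm",
    "fit_model",
    "loglik_quadrature",
    "predict_proportion",
]

# Standardised-scale coefficient magnitude beyond which the likelihood is
# effectively flat in a direction -> complete separation.
_SEPARATION_BETA = 12.0


class SeparationError(RuntimeError):
    """Complete separation: some covariate perfectly predicts maturity."""


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate maturity model.

    ``lat_term`` is ``"spline"`` (continuous latitude, ``lat_df`` degrees of
    freedom), ``"discrete3"`` (three latitudinal bands) or ``None``;
    interactions require the corresponding main effect.
    """

    predictor: Literal["length", "age"] = "length"
    predictor_df: int = 2
    lat_term: Optional[Literal["spline", "discrete3"]] = None
    lat_df: int = 2
    lon_df: Optional[int] = None
    season_levels: Literal[2, 4] = 2
    lat_season_interaction: bool = False
    lon_season_interaction: bool = False
    band_edges: tuple = DEFAULT_BAND_EDGES_DEGS

    def __post_init__(self) -> None:
        if self.predictor not in ("length", "age"):
            raise ValueError(f"predictor must be length or age, got {self.predictor}")
        if self.season_levels not in (2, 4):
            raise ValueError(f"season_levels must be 2 or 4, got {self.season_levels}")
        if self.lat_season_interaction and self.lat_term is None:
            raise ValueError("lat_season_interaction requires a latitude term")
        if self.lon_season_interaction and self.lon_df is None:
            raise ValueError("lon_season_interaction requires a longitude term")

    def model_id(self) -> str:
        parts = [f"{self.predictor}{self.predictor_df}"]
        if self.lat_term == "spline":
            parts.append(f"lat{self.lat_df}")
        elif self.lat_term == "discrete3":
            parts.append("latD3")
        if self.lon_df is not None:
            parts.append(f"lon{self.lon_df}")
        parts.append(f"ssn{self.season_levels}")
        if self.lat_season_interaction:
            parts.append("latxssn")
        if self.lon_season_interaction:
            parts.append("lonxssn")
        return "_".join(parts)


_PREDICTOR_COLUMNS = {"length": "fork_length_cm", "age": "age_years"}


@dataclass
class DesignInfo:
    """Everything needed to rebuild the design matrix on new data."""

    spec: ModelSpec
    bases: dict = field(default_factory=dict)  # variable -> SplineBasis
    column_names: list = field(default_factory=list)

    def _required_columns(self) -> list[str]:
        cols = [_PREDICTOR_COLUMNS[self.spec.predictor], "month"]
        if self.spec.lat_term is not None:
            cols.append("latitude_degS")
        if self.spec.lon_df is not None:
            cols.append("longitude_degE")
        return cols

    def build(
        self, data: pd.DataFrame, training: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, extrapolation flags).  When ``training`` is true the
        spline bases are (re)fitted to ``data``; otherwise the stored knots
        are reused and rows outside a training span are flagged."""
        spec = self.spec
        missing = [c for c in self._required_columns() if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing required columns: {missing}")
        n = len(data)
        blocks = [np.ones((n, 1))]
        names = ["intercept"]
        extrapolated = np.zeros(n, dtype=bool)

        def spline_block(variable: str, column: str, df: int) -> np.ndarray:
            nonlocal extrapolated
            x = data[column].to_numpy(dtype=float)
            if np.any(~np.isfinite(x)):
                raise ValueError(f"missing or non-finite values in {column}")
            if training:
                self.bases[variable] = spline_basis(x, SplineSpec(variable, df))
            basis = self.bases[variable]
            extrapolated |= (x < basis.train_min) | (x > basis.train_max)
            names.extend(basis.column_names())
            return basis.transform(x)

        blocks.append(
            spline_block(
                spec.predictor, _PREDICTOR_COLUMNS[spec.predictor], spec.predictor_df
            )
        )

        lat_cols = None
        if spec.lat_term == "spline":
            lat_cols = spline_block("latitude", "latitude_degS", spec.lat_df)
            blocks.append(lat_cols)
            lat_names = self.bases["latitude"].column_names()
        elif spec.lat_term == "discrete3":
            band = latitude_band(
                data["latitude_degS"].to_numpy(dtype=float), edges=spec.band_edges
            )
            lat_cols = np.column_stack([(band == 2).astype(float),
                                        (band == 3).astype(float)])
            blocks.append(lat_cols)
            lat_names = ["lat_band2", "lat_band3"]
            names.extend(lat_names)

        if spec.lon_df is not None:
            lon_cols = spline_block("longitude", "longitude_degE", spec.lon_df)
            blocks.append(lon_cols)
            lon_names = self.bases["longitude"].column_names()
        else:
            lon_cols = None

        month = data["month"].to_numpy()
        if spec.season_levels == 2:
            # reference = season 2 (Apr-Sep); one dummy for Oct-Mar
            season = season_2level(month)
            season_cols = (season == 1).astype(float)[:, None]
            season_names = ["season1"]
        else:
            # reference = Jan-Mar; dummies for Q2, Q3, Q4
            quarter = season_4level(month)
            season_cols = np.column_stack(
                [(quarter == q).astype(float) for q in (2, 3, 4)]
            )
            season_names = ["quarter2", "quarter3", "quarter4"]
        blocks.append(season_cols)
        names.extend(season_names)

        if spec.lat_season_interaction:
            inter = _products(lat_cols, season_cols)
            blocks.append(inter)
            names.extend(
                [f"{a}:{b}" for b in season_names for a in lat_names]
            )
        if spec.lon_season_interaction:
            inter = _products(lon_cols, season_cols)
            blocks.append(inter)
            names.extend(
                [f"{a}:{b}" for b in season_names for a in lon_names]
            )

        X = np.hstack(blocks)
        if training:
            self.column_names = names
        return X, extrapolated


def _products(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    # column-wise products: for each right column, all left columns
    return np.hstack([left * right[:, [j]] for j in range(right.shape[1])])


@dataclass
class DesignMatrices:
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # integer codes 0..n_groups-1
    group_labels: np.ndarray
    column_names: list
    design_info: DesignInfo


def build_design(records: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build the fixed-effect design, response and grouping for a model.

    ``records`` must carry the covariates the spec requires plus ``set_id``
    and a ``maturity`` column coded 1 = mature (accepts 0/1, booleans, or
    the tokens mature/immature).
    """
    if "maturity" not in records.columns:
        raise ValueError("data is missing required columns: ['maturity']")
    if "set_id" not in records.columns:
        raise ValueError("data is missing required columns: ['set_id']")
    y = _coerce_maturity(records["maturity"])
    info = DesignInfo(spec=spec)
    X, _ = info.build(records, training=True)
    group_labels, groups = np.unique(records["set_id"].to_numpy(), return_inverse=True)
    return DesignMatrices(
        X=X,
        y=y,
        groups=groups,
        group_labels=group_labels,
        column_names=list(info.column_names),
        design_info=info,
    )


def _coerce_maturity(col: pd.Series) -> np.ndarray:
    vals = col.to_numpy()
    if vals.dtype.kind in "biuf":
        y = vals.astype(float)
    else:
        mapping = {"mature": 1.0, "immature": 0.0, "1": 1.0, "0": 0.0,
                   "true": 1.0, "false": 0.0}
        y = np.array([mapping.get(str(v).strip().lower(), np.nan) for v in vals])
    if np.any(~np.isin(y, (0.0, 1.0))):
        raise ValueError("maturity must be binary (1 = mature, 0 = immature)")
    return y


@dataclass
class GLMMFit:
    """A fitted binomial logit mixed model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_set: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    column_names: list
    design_info: Optional[DesignInfo] = None
    spec: Optional[ModelSpec] = None

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se_beta()}, index=self.column_names
        )


# ---------------------------------------------------------------------------
# Laplace machinery


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log p(y | eta) elementwise, numerically safe
    return y * eta - np.logaddexp(0.0, eta)


def _conditional_modes(
    eta: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    sigma: float,
    b0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton solve for the per-group conditional modes, vectorised.

    Returns (modes b, curvatures H_g = -d2/db2 of the joint log density,
    converged flag).  The inner problem is strictly concave so damped
    Newton converges; steps are halved when the gradient norm fails to
    decrease.
    """
    inv_var = 1.0 / sigma**2
    b = b0.copy()

    def grad_at(bvec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = expit(eta + bvec[groups])
        g = np.bincount(groups, weights=y - p, minlength=n_groups) - bvec * inv_var
        w = np.bincount(groups, weights=p * (1 - p), minlength=n_groups) + inv_var
        return g, w

    g, w = grad_at(b)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            return b, w, True
        step = g / w
        # step-halving on groups whose gradient magnitude grew
        for _ in range(30):
            b_new = b + step
            g_new, w_new = grad_at(b_new)
            worse = np.abs(g_new) > np.abs(g)
            if not np.any(worse & (np.abs(g) > tol)):
                break
            step = np.where(worse, step / 2.0, step)
        b, g, w = b_new, g_new, w_new
    return b, w, bool(np.max(np.abs(g)) < 1e-6)


def _laplace_loglik(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    beta: np.ndarray,
    sigma: float,
    b_cache: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Laplace-approximate marginal log-likelihood; returns (ll, modes)."""
    eta = X @ beta
    if sigma < 1e-8:
        # boundary: the integral collapses and the model is a plain GLM
        return float(np.sum(_bernoulli_loglik(eta, y))), np.zeros(n_groups)
    b0 = b_cache if b_cache is not None else np.zeros(n_groups)
    b, w, _ = _conditional_modes(eta, y, groups, n_groups, sigma, b0)
    eta_b = eta + b[groups]
    joint = (
        np.sum(_bernoulli_loglik(eta_b, y))
        - 0.5 * np.sum(b**2) / sigma**2
    )
    # integral of exp(joint density) over each b_g: sqrt(2*pi / w_g);
    # the Gaussian prior normaliser contributes -log(sigma sqrt(2*pi)) per group
    ll = joint - n_groups * np.log(sigma) - 0.5 * np.sum(np.log(w))
    return float(ll), b


def fit_logistic_glmm(
    design: np.ndarray,
    response: np.ndarray,
    groups: Sequence,
    column_names: Optional[list] = None,
    sigma_start: float = 0.3,
    sigma_max: float = 10.0,
    design_info: Optional[DesignInfo] = None,
) -> GLMMFit:
    """Fit the mixed logit model by maximising the Laplace marginal likelihood.

    ``design`` must include an intercept column.  ``groups`` are fishing-set
    labels; fish sharing a label share a Gaussian random intercept.  The
    returned covariance of the fixed effects is the inverse observed
    information with the variance component held at its estimate (the usual
    mixed-model convention).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    group_labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = group_labels.size
    n, p = X.shape
    if n != y.size or n != gidx.size:
        raise ValueError("design, response and groups must have equal length")
    if n_groups < 2:
        raise ValueError("need at least 2 groups to identify a set effect")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("response must contain both mature and immature fish")
    if column_names is None:
        column_names = [f"x{j}" for j in range(p)]

    # standardise non-intercept columns for conditioning; map back at the end
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    is_intercept = scales < 1e-12
    means[is_intercept] = 0.0
    scales[is_intercept] = 1.0
    Xs = (X - means) / scales

    beta0 = _irls_logistic(Xs, y, column_names)
    theta0 = np.concatenate([beta0, [sigma_start]])

    b_cache = np.zeros(n_groups)

    def negll(theta: np.ndarray) -> float:
        nonlocal b_cache
        ll, b_cache = _laplace_loglik(
            Xs, y, gidx, n_groups, theta[:-1], theta[-1], b_cache
        )
        return -ll

    bounds = [(None, None)] * p + [(0.0, sigma_max)]
    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    beta_s, sigma = res.x[:-1], float(res.x[-1])
    _check_separation(beta_s, column_names)
    ll = -float(res.fun)
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            f"GLMM optimiser did not report convergence: {res.message}",
            ConvergenceWarning,
        )

    cov_s = _beta_covariance(Xs, y, gidx, n_groups, beta_s, sigma)
    # undo standardisation: beta = A beta_s with A as below
    A = np.diag(1.0 / scales)
    icol = int(np.argmax(is_intercept)) if np.any(is_intercept) else 0
    A[icol, :] = -means / scales
    A[icol, icol] = 1.0
    beta = A @ beta_s
    cov = A @ cov_s @ A.T
    cov = 0.5 * (cov + cov.T)

    return GLMMFit(
        beta=beta,
        cov_beta=cov,
        sigma_set=sigma,
        loglik=ll,
        n_obs=n,
        n_params=p + 1,
        converged=converged,
        column_names=list(column_names),
        design_info=design_info,
        spec=design_info.spec if design_info is not None else None,
    )


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, names: list, max_iter: int = 50
) -> np.ndarray:
    """Plain logistic regression by Fisher scoring; also the separation probe."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + 1e-8 * np.eye(p)
        beta_new = np.linalg.solve(H, XtW @ z)
        _check_separation(beta_new, names)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _check_separation(beta_std: np.ndarray, names: list) -> None:
    if np.max(np.abs(beta_std)) > _SEPARATION_BETA:
        j = int(np.argmax(np.abs(beta_std)))
        raise SeparationError(
            f"complete separation detected: coefficient for {names[j]!r} "
            "diverges (this covariate perfectly predicts maturity)"
        )


def _beta_covariance(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    beta: np.ndarray,
    sigma: float,
    rel_step: float = 1e-5,
) -> np.ndarray:
    """Inverse observed information of beta (sigma fixed), central differences."""
    p = beta.size

    def f(bv: np.ndarray) -> float:
        ll, _ = _laplace_loglik(X, y, groups, n_groups, bv, sigma)
        return ll

    h = rel_step * np.maximum(np.abs(beta), 1.0)
    H = np.empty((p, p))
    f0 = f(beta)
    # diagonal then off-diagonal central second differences
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        fp[i] = f(beta + e)
        fm[i] = f(beta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(beta + ei + ej)
            fmm = f(beta - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return cov


def fit_model(records: pd.DataFrame, spec: ModelSpec, **kwargs) -> GLMMFit:
    """Convenience wrapper: build the design from records and fit."""
    dm = build_design(records, spec)
    return fit_logistic_glmm(
        dm.X,
        dm.y,
        dm.groups,
        column_names=dm.column_names,
        design_info=dm.design_info,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Quadrature oracle


def loglik_quadrature(
    design: np.ndarray,
    response: np.ndarray,
    groups: Sequence,
    beta: np.ndarray,
    sigma: float,
    n_nodes: int = 21,
    adaptive: bool = True,
) -> float:
    """Marginal log-likelihood by (adaptive) Gauss-Hermite quadrature.

    Intended as a high-accuracy cross-check of the Laplace approximation on
    small problems (<= a few tens of sets).  With ``adaptive`` the rule is
    centred and scaled at each set's conditional mode.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = int(gidx.max()) + 1
    if n_groups > 30:
        raise ValueError("quadrature oracle is restricted to <= 30 groups")
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    if sigma < 1e-12:
        return float(np.sum(_bernoulli_loglik(eta, y)))

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    if adaptive:
        b_hat, w_curv, _ = _conditional_modes(
            eta, y, gidx, n_groups, sigma, np.zeros(n_groups)
        )
        tau = 1.0 / np.sqrt(w_curv)
    else:
        b_hat = np.zeros(n_groups)
        tau = np.full(n_groups, sigma / np.sqrt(2.0))

    total = 0.0
    log_prior_norm = -np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    for g in range(n_groups):
        rows = gidx == g
        bg = b_hat[g] + np.sqrt(2.0) * tau[g] * nodes  # (n_nodes,)
        eta_g = eta[rows][:, None] + bg[None, :]
        ll_cond = np.sum(_bernoulli_loglik(eta_g, y[rows][:, None]), axis=0)
        log_integrand = (
            ll_cond
            - 0.5 * bg**2 / sigma**2
            + log_prior_norm
            + nodes**2
            + np.log(np.sqrt(2.0) * tau[g])
        )
        total += logsumexp(log_integrand, b=weights)
    return float(total)


# ---------------------------------------------------------------------------
# Prediction


def predict_proportion(
    fit: GLMMFit,
    newdata: pd.DataFrame,
    level: float = 0.95,
    marginalize: bool = False,
    n_nodes: int = 21,
) -> pd.DataFrame:
    """Predicted proportion mature with a logit-scale Wald interval.

    Predictions are for a typical set (random intercept = 0) unless
    ``marginalize`` is set, in which case the set effect is integrated out
    by Gauss-Hermite quadrature (population-averaged proportions).  Rows
    whose covariates fall outside the training span of a spline are flagged
    in the ``extrapolated`` column.
    """
    if fit.design_info is None:
        raise ValueError("fit carries no design info; build it via fit_model")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    X, extrapolated = fit.design_info.build(newdata, training=False)
    eta = X @ fit.beta
    var_eta = np.einsum("ij,jk,ik->i", X, fit.cov_beta, X)
    se = np.sqrt(np.clip(var_eta, 0.0, None))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    lo_eta, hi_eta = eta - z * se, eta + z * se
    if marginalize and fit.sigma_set > 1e-8:
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        scale = np.sqrt(2.0) * fit.sigma_set
        wnorm = weights / np.sqrt(np.pi)

        def avg(e):
            return expit(e[:, None] + scale * nodes[None, :]) @ wnorm

        prop, lo, hi = avg(eta), avg(lo_eta), avg(hi_eta)
    else:
        prop, lo, hi = expit(eta), expit(lo_eta), expit(hi_eta)
    out = newdata.copy()
    out["proportion"] = prop
    out["se_logit"] = se
    out["ci_low"] = np.clip(lo, 0.0, 1.0)
    out["ci_high"] = np.clip(hi, 0.0, 1.0)
    out["extrapolated"] = extrapolated
    return out
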