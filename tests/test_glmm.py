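"""Mixed logit model: design construction, Laplace fit, oracles, prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from matogive.glmm import (
    DesignInfo,
    GLMMFit,
    ModelSpec,
    SeparationError,
    build_design,
    fit_logistic_glmm,
    fit_model,
    loglik_quadrature,
    predict_proportion,
)
from matogive.splines import SplineSpec, spline_basis


def _records(n=200, seed=0, with_age=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "set_id": rng.integers(0, 20, n),
            "month": rng.integers(1, 13, n),
            "latitude_degS": rng.uniform(10, 40, n),
            "longitude_degE": rng.uniform(155, 230, n),
            "fork_length_cm": rng.uniform(50, 110, n),
        }
    )
    df["maturity"] = (
        rng.random(n) < expit(0.2 * (df["fork_length_cm"] - 87))
    ).astype(int)
    if with_age:
        df["age_years"] = rng.uniform(1, 12, n)
    return df


@pytest.mark.parametrize(
    "spec, n_cols",
    [
        # intercept + length spline + season dummy
        (ModelSpec(predictor_df=2, season_levels=2), 1 + 2 + 1),
        # + discrete latitude (2 dummies) and its interaction with season
        (
            ModelSpec(
                predictor_df=2,
                lat_term="discrete3",
                season_levels=2,
                lat_season_interaction=True,
            ),
            1 + 2 + 2 + 1 + 2,
        ),
        # latitude spline, 4 seasons, both interactions
        (
            ModelSpec(
                predictor_df=6,
                lat_term="spline",
                lat_df=2,
                lon_df=1,
                season_levels=4,
                lat_season_interaction=True,
                lon_season_interaction=True,
            ),
            1 + 6 + 2 + 1 + 3 + 6 + 3,
        ),
    ],
)
def test_design_column_counts(spec, n_cols):
    dm = build_design(_records(), spec)
    assert dm.X.shape[1] == n_cols
    assert len(dm.column_names) == n_cols


def test_design_missing_covariate_error():
    records = _records().drop(columns=["age_years"], errors="ignore")
    with pytest.raises(ValueError, match="age_years"):
        build_design(records, ModelSpec(predictor="age", predictor_df=2))


def test_interaction_requires_main_effect():
    with pytest.raises(ValueError, match="lat_season_interaction"):
        ModelSpec(lat_term=None, lat_season_interaction=True)


def test_all_immature_accepted_at_design_stage():
    records = _records()
    records["maturity"] = 0
    dm = build_design(records, ModelSpec(predictor_df=1))
    assert dm.y.sum() == 0
    with pytest.raises(ValueError, match="both mature and immature"):
        fit_logistic_glmm(dm.X, dm.y, dm.groups)


def test_sigma_zero_fit_equals_plain_logistic(glmm_dataset):
    """With the set-effect SD pinned at zero the model is a GLM."""
    X, y, groups = glmm_dataset
    ours = fit_logistic_glmm(X, y, groups, sigma_start=0.0, sigma_max=0.0)
    oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(ours.beta, oracle.params, atol=1e-6)
    np.testing.assert_allclose(ours.loglik, oracle.llf, atol=1e-8)
    assert ours.sigma_set == 0.0


def test_glm_oracle_recovery_when_no_set_effect():
    """Data generated without a set effect: beta within 2 joint SEs of the
    plain logistic-regression oracle fitted to the same data."""
    rng = np.random.default_rng(3)
    n = 2000
    groups = rng.integers(0, 100, n)
    L = rng.normal(85, 8, n)
    y = (rng.random(n) < expit(0.2 * (L - 87))).astype(float)
    X = np.column_stack([np.ones(n), L - 85])
    ours = fit_logistic_glmm(X, y, groups)
    oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    diff = ours.beta - oracle.params
    cov = np.asarray(oracle.cov_params())
    d2 = float(diff @ np.linalg.solve(cov, diff))
    assert d2 < 4.0  # within 2 joint standard errors
    assert ours.sigma_set < 0.15


def test_laplace_close_to_quadrature_at_optimum():
    """5 sets x 8 fish: Laplace within 1% of adaptive Gauss-Hermite."""
    rng = np.random.default_rng(5)
    groups = np.repeat(np.arange(5), 8)
    b = rng.normal(0, 0.6, 5)
    L = rng.normal(85, 8, 40)
    y = (rng.random(40) < expit(0.2 * (L - 85) + b[groups])).astype(float)
    X = np.column_stack([np.ones(40), L - 85])
    fit = fit_logistic_glmm(X, y, groups)
    llq = loglik_quadrature(X, y, groups, fit.beta, fit.sigma_set, n_nodes=25)
    assert abs(fit.loglik - llq) / abs(llq) < 1e-2


def test_quadrature_node_count_stability(glmm_dataset):
    X, y, groups = glmm_dataset
    fit = fit_logistic_glmm(X, y, groups)
    ll21 = loglik_quadrature(X, y, groups, fit.beta, max(fit.sigma_set, 0.3), 21)
    ll41 = loglik_quadrature(X, y, groups, fit.beta, max(fit.sigma_set, 0.3), 41)
    assert abs(ll21 - ll41) < 1e-8


def test_quadrature_sigma_zero_is_bernoulli(glmm_dataset):
    X, y, groups = glmm_dataset
    beta = np.array([0.1, 0.15])
    eta = X @ beta
    exact = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    assert loglik_quadrature(X, y, groups, beta, 0.0) == pytest.approx(exact)


def test_quadrature_refuses_many_groups():
    X = np.ones((40, 1))
    y = np.tile([0.0, 1.0], 20)
    with pytest.raises(ValueError, match="30 groups"):
        loglik_quadrature(X, y, np.arange(40), np.array([0.0]), 0.5)


def test_separation_raises():
    y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1] * 3)
    x = np.where(y > 0, 1.0, -1.0) + np.linspace(0, 0.01, y.size)
    X = np.column_stack([np.ones_like(x), x])
    with pytest.raises(SeparationError):
        fit_logistic_glmm(X, y, np.arange(y.size) % 4, column_names=["int", "x"])


def test_loglik_at_optimum_beats_start(glmm_dataset):
    from matogive.glmm import _laplace_loglik

    X, y, groups = glmm_dataset
    n_groups = int(groups.max()) + 1
    fit = fit_logistic_glmm(X, y, groups)
    ll_start, _ = _laplace_loglik(X, y, groups, n_groups, np.zeros(2), 0.3)
    assert fit.loglik >= ll_start


def _fitted_model(n=600, seed=4):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "set_id": rng.integers(0, 40, n),
            "month": rng.integers(1, 13, n),
            "latitude_degS": rng.uniform(10, 40, n),
            "fork_length_cm": rng.uniform(55, 110, n),
        }
    )
    b = rng.normal(0, 0.5, 40)
    eta = 0.2 * (df["fork_length_cm"] - 87) + b[df["set_id"]]
    df["maturity"] = (rng.random(n) < expit(eta)).astype(int)
    return df, fit_model(df, ModelSpec(predictor_df=2, season_levels=2))


def test_prediction_intervals_bracket_and_bound():
    df, fit = _fitted_model()
    basis = fit.design_info.bases["length"]
    new = pd.DataFrame(
        {
            "fork_length_cm": np.linspace(basis.train_min, basis.train_max, 30),
            "month": 6,
        }
    )
    pred = predict_proportion(fit, new)
    assert ((pred["ci_low"] <= pred["proportion"]) & (pred["proportion"] <= pred["ci_high"])).all()
    assert pred[["proportion", "ci_low", "ci_high"]].min().min() >= 0.0
    assert pred[["proportion", "ci_low", "ci_high"]].max().max() <= 1.0
    assert not pred["extrapolated"].any()
    out = predict_proportion(fit, new.assign(fork_length_cm=120.0))
    assert out["extrapolated"].all()


def test_prediction_invariant_to_row_order():
    df, fit = _fitted_model()
    new = pd.DataFrame(
        {"fork_length_cm": np.linspace(60, 100, 21), "month": 2}
    )
    fwd = predict_proportion(fit, new)["proportion"].to_numpy()
    rev = predict_proportion(fit, new.iloc[::-1])["proportion"].to_numpy()
    np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)


def test_zero_coefficients_predict_half():
    df, fit = _fitted_model()
    fit.beta = np.zeros_like(fit.beta)
    pred = predict_proportion(
        fit, pd.DataFrame({"fork_length_cm": [70.0, 90.0], "month": 1})
    )
    np.testing.assert_allclose(pred["proportion"], 0.5)


def test_se_matches_set_bootstrap_within_25pct():
    """Model-based logit SE at a training point vs a nonparametric
    bootstrap over fishing sets (the resampling unit)."""
    rng = np.random.default_rng(9)
    n_sets, nf = 30, 12
    groups = np.repeat(np.arange(n_sets), nf)
    b = rng.normal(0, 0.5, n_sets)
    L = rng.normal(85, 8, n_sets * nf)
    y = (rng.random(L.size) < expit(0.2 * (L - 85) + b[groups])).astype(float)
    X = np.column_stack([np.ones_like(L), L - 85])
    fit = fit_logistic_glmm(X, y, groups)
    x0 = np.array([1.0, 5.0])  # prediction point: 90 cm
    se_model = float(np.sqrt(x0 @ fit.cov_beta @ x0))

    etas = []
    for _ in range(200):
        sets = rng.integers(0, n_sets, n_sets)
        rows = np.concatenate([np.flatnonzero(groups == s) for s in sets])
        gboot = np.repeat(np.arange(n_sets), [np.sum(groups == s) for s in sets])
        try:
            bfit = fit_logistic_glmm(X[rows], y[rows], gboot)
        except (SeparationError, ValueError):
            continue
        etas.append(float(x0 @ bfit.beta))
    se_boot = float(np.std(etas, ddof=1))
    assert abs(se_model - se_boot) / se_boot < 0.25


def test_marginalized_predictions_are_flatter():
    df, fit = _fitted_model()
    new = pd.DataFrame({"fork_length_cm": [70.0, 100.0], "month": 6})
    cond = predict_proportion(fit, new)["proportion"].to_numpy()
    marg = predict_proportion(fit, new, marginalize=True)["proportion"].to_numpy()
    # averaging over the set effect pulls extreme probabilities toward 1/2
    assert marg[0] >= cond[0] - 1e-12
    assert marg[1] <= cond[1] + 1e-12
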