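"""AICc, Akaike weights, candidate grids, and L50 summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from matogive.glmm import DesignInfo, GLMMFit, ModelSpec, fit_model
from matogive.selection import (
    aicc,
    akaike_weights,
    candidate_grid,
    compare_models,
    comparison_table,
    head_to_head,
    l50_by_latitude,
    l50_from_curve,
)
from matogive.splines import SplineSpec, spline_basis


def test_aicc_closed_form():
    # -2(-100) + 2*3 + 2*3*4/(100-3-1) = 206.25
    assert aicc(-100.0, 3, 100) == pytest.approx(206.25)


def test_aicc_large_n_limit_is_aic():
    assert aicc(-100.0, 3, 10**9) == pytest.approx(206.0, abs=1e-6)


def test_aicc_small_sample_boundary():
    with pytest.raises(ValueError, match="undefined"):
        aicc(-10.0, 8, 10)  # k = n - 2


def test_akaike_weights_symmetry_and_normalisation():
    np.testing.assert_allclose(akaike_weights([12.0, 12.0]), [0.5, 0.5])


def test_akaike_weights_of_published_deltas():
    """Renormalising the six published Delta-AICc values: the direct
    formula, evaluated independently here, fixes the expected weights."""
    deltas = np.array([0.0, 0.66, 2.62, 5.29, 6.07, 7.19])
    raw = np.exp(-deltas / 2.0)
    expected = raw / raw.sum()  # independent one-line oracle
    got = akaike_weights(1000.0 + deltas)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert got[0] == pytest.approx(0.4683, abs=5e-4)


@given(st.lists(st.floats(0, 100), min_size=1, max_size=12), st.floats(-50, 50))
def test_akaike_weights_sum_to_one_and_shift_invariant(values, shift):
    w = akaike_weights(values)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(w, akaike_weights(np.array(values) + shift), atol=1e-12)


@given(st.lists(st.floats(0, 30), min_size=3, max_size=8))
def test_subset_renormalisation_never_decreases_weights(values):
    """Dropping candidates can only increase each survivor's weight."""
    full = akaike_weights(values)
    sub = akaike_weights(values[:-1])
    assert np.all(sub >= full[:-1] - 1e-12)


def test_candidate_grid_covers_published_axes():
    specs = candidate_grid()
    assert len(specs) >= 24
    ids = {s.model_id() for s in specs}
    assert len(ids) == len(specs)  # no duplicates
    # the published best structure is in the grid
    assert any(
        s.predictor_df == 2
        and s.lat_term == "spline"
        and s.lat_df == 2
        and s.lon_df is None
        and s.season_levels == 2
        and s.lat_season_interaction
        for s in specs
    )


def _clustered_records(n_sets=60, nf=25, seed=0, lat_effect=0.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_sets), nf)
    n = groups.size
    df = pd.DataFrame(
        {
            "set_id": groups,
            "month": rng.integers(1, 13, n),
            "latitude_degS": rng.uniform(10, 40, n),
            "longitude_degE": rng.uniform(155, 230, n),
            "fork_length_cm": rng.uniform(55, 110, n),
        }
    )
    b = rng.normal(0, 0.4, n_sets)
    eta = (
        0.2 * (df["fork_length_cm"] - 87)
        + lat_effect * (df["latitude_degS"] - 25)
        + b[groups]
    )
    df["maturity"] = (rng.random(n) < expit(eta)).astype(int)
    df["age_years"] = np.clip(
        (df["fork_length_cm"] - 40) / 8 + rng.normal(0, 1.5, n), 0.5, None
    )
    return df


def test_compare_models_ranks_and_weights():
    records = _clustered_records(lat_effect=0.15, seed=2)
    specs = [
        ModelSpec(predictor_df=1),
        ModelSpec(predictor_df=1, lat_term="spline", lat_df=2),
        ModelSpec(predictor_df=1, lat_term="spline", lat_df=2),  # duplicate
    ]
    rows = compare_models(records, specs)
    assert rows[0].delta_aicc == 0.0
    assert sum(r.akaike_weight for r in rows) == pytest.approx(1.0, abs=1e-12)
    # duplicated spec: identical AICc and shared weight
    dup = [r for r in rows if r.spec.lat_term == "spline"]
    assert abs(dup[0].aicc - dup[1].aicc) < 1e-8
    assert dup[0].akaike_weight == pytest.approx(dup[1].akaike_weight, abs=1e-10)
    # the latitude model generated the data, so it should rank first
    assert rows[0].spec.lat_term == "spline"
    table = comparison_table(rows)
    assert list(table["model"]) == [1, 2, 3]


def test_compare_models_invariant_to_candidate_order():
    records = _clustered_records(seed=3)
    specs = [ModelSpec(predictor_df=1), ModelSpec(predictor_df=2)]
    fwd = compare_models(records, specs)
    rev = compare_models(records, specs[::-1])
    assert [r.model_id for r in fwd] == [r.model_id for r in rev]
    np.testing.assert_allclose(
        [r.aicc for r in fwd], [r.aicc for r in rev], atol=1e-8
    )


def test_selection_prefers_generating_model():
    """The latitude-free truth should beat the latitude model most times."""
    wins = 0
    for seed in range(6):
        records = _clustered_records(n_sets=50, nf=30, seed=seed, lat_effect=0.0)
        rows = compare_models(
            records,
            [ModelSpec(predictor_df=1), ModelSpec(predictor_df=1, lat_term="spline", lat_df=2)],
        )
        wins += rows[0].spec.lat_term is None
    assert wins >= 4


def test_head_to_head_length_beats_noisy_age():
    wins = 0
    for seed in range(5):
        records = _clustered_records(n_sets=50, nf=30, seed=seed)
        rows = head_to_head(records, predictor_df=2, season_levels=2)
        weights = {r.spec.predictor: r.akaike_weight for r in rows}
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)
        wins += rows[0].spec.predictor == "length"
    assert wins >= 4


def test_head_to_head_requires_complete_ages():
    records = _clustered_records(seed=1)
    records.loc[0, "age_years"] = np.nan
    with pytest.raises(ValueError, match="age"):
        head_to_head(records)


def _synthetic_fit_with_known_curve(b0=-17.4, b1=0.2):
    """A fitted-model shell whose linear predictor is b0 + b1 * length."""
    rng = np.random.default_rng(0)
    lengths = rng.uniform(60, 110, 500)
    spec = ModelSpec(predictor_df=1, season_levels=2)
    info = DesignInfo(spec=spec)
    frame = pd.DataFrame({"fork_length_cm": lengths, "month": 6})
    info.build(frame, training=True)
    center = info.bases["length"].knots[0]
    beta = np.array([b0 + b1 * center, b1, 0.0])  # intercept, length, season1
    return GLMMFit(
        beta=beta,
        cov_beta=np.eye(3) * 1e-6,
        sigma_set=0.0,
        loglik=0.0,
        n_obs=500,
        n_params=4,
        converged=True,
        column_names=info.column_names,
        design_info=info,
        spec=spec,
    )


def test_l50_closed_form_logistic():
    fit = _synthetic_fit_with_known_curve()
    out = l50_by_latitude(fit, [20.0, 30.0], season=2)
    np.testing.assert_allclose(out["L50"], 87.0, atol=0.01)
    assert ((out["ci_low"] <= out["L50"]) & (out["L50"] <= out["ci_high"])).all()


def test_l50_missing_when_no_crossing():
    fit = _synthetic_fit_with_known_curve(b0=5.0, b1=0.001)  # always mature
    out = l50_by_latitude(fit, [25.0], season=2)
    assert np.isnan(out.loc[0, "L50"])
    assert "no 0.5 crossing" in out.loc[0, "reason"]


def test_l50_curve_recovery_against_latitude_gradient():
    """True L50 linear in latitude: the fitted latitude-spline model should
    recover the L50-by-latitude curve within 2 cm across the span."""
    from matogive import PopulationParams, simulate_population

    params = PopulationParams(
        n_sets=1000,
        fish_per_set_mean=40,
        migration_enabled=False,
        sample_fraction=1.0,
        seed=21,
    )
    pop = simulate_population(params)
    fem = pop[pop["sex"] == "F"]
    fit = fit_model(
        fem,
        ModelSpec(
            predictor_df=2,
            lat_term="spline",
            lat_df=2,
            season_levels=2,
            lat_season_interaction=True,
        ),
    )
    lats = np.array([15.0, 20.0, 25.0, 30.0, 35.0])
    out = l50_by_latitude(fit, lats, season=2)
    truth = params.l50(lats, 2)
    np.testing.assert_allclose(out["L50"].to_numpy(), truth, atol=2.0)
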