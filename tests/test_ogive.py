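"""Abundance weighting, the combined ogive, and its variance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from matogive.ogive import (
    OgiveEstimate,
    area_season_ogives,
    combine_weighted,
    compute_weights,
    fit_unweighted,
    length_at_quantile,
)
from matogive.simulate import PopulationParams, derive_abundance_inputs, simulate_population


def _tables(N_vals, p_vals, f_vals, mids=(78.0,)):
    rows_N, rows_p, rows_f = [], [], []
    for a, Nv in enumerate(N_vals, start=1):
        rows_N.append({"area": a, "season": 1, "N": Nv})
        for m in mids:
            rows_p.append(
                {"length_class_mid": m, "area": a, "season": 1, "p": p_vals[a - 1]}
            )
            rows_f.append(
                {"length_class_mid": m, "area": a, "season": 1, "f": f_vals[a - 1]}
            )
    return pd.DataFrame(rows_N), pd.DataFrame(rows_p), pd.DataFrame(rows_f)


def test_weights_symmetric_case():
    N, p, f = _tables([1.0, 1.0], [0.5, 0.5], [0.5, 0.5])
    W = compute_weights(N, p, f)
    np.testing.assert_allclose(W["W"], [0.5, 0.5])


def test_weights_hand_calculation():
    # raw = N*p*f = (3*0.2*0.5, 1*0.4*0.25) = (0.3, 0.1) -> W = (0.75, 0.25)
    N, p, f = _tables([3.0, 1.0], [0.2, 0.4], [0.5, 0.25])
    W = compute_weights(N, p, f)
    np.testing.assert_allclose(W.sort_values("area")["W"], [0.75, 0.25])


def test_weights_validation():
    N, p, f = _tables([1.0, -1.0], [0.5, 0.5], [0.5, 0.5])
    with pytest.raises(ValueError, match="non-negative"):
        compute_weights(N, p, f)
    N2 = pd.DataFrame({"area": [1], "season": [1], "N": [0.0]})
    _, p2, f2 = _tables([1.0], [1.0], [1.0])
    with pytest.raises(ValueError, match="no positive entry"):
        compute_weights(N2, p2, f2)


@given(
    st.lists(st.floats(0.01, 10), min_size=2, max_size=3),
    st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
    st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
)
def test_weights_sum_to_one(Ns, ps, fs):
    k = len(Ns)
    N, p, f = _tables(Ns, ps[:k], fs[:k])
    W = compute_weights(N, p, f)
    assert W["W"].sum() == pytest.approx(1.0, abs=1e-12)


def test_missing_cells_renormalised():
    N, p, f = _tables([2.0, 1.0], [0.5, 0.5], [0.5, 0.5])
    f.loc[f["area"] == 2, "f"] = np.nan  # area 2 has no sex-ratio data
    W = compute_weights(N, p, f)
    assert W.loc[W["area"] == 1, "W"].iloc[0] == pytest.approx(1.0)
    assert np.isnan(W.loc[W["area"] == 2, "W"].iloc[0])


def _area_frame(p_hats, var_ps, mids=(78.0,)):
    rows = []
    for a, (ph, vp) in enumerate(zip(p_hats, var_ps), start=1):
        for m in mids:
            rows.append(
                {
                    "length_class_mid": m,
                    "area": a,
                    "season": 1,
                    "p_hat": ph,
                    "var_p": vp,
                }
            )
    return pd.DataFrame(rows)


def test_combine_simple_average_and_degenerate_weight():
    area = _area_frame([0.2, 0.8], [0.01, 0.04])
    N, p, f = _tables([1.0, 1.0], [0.5, 0.5], [0.5, 0.5])
    W = compute_weights(N, p, f)
    est = combine_weighted(area, W)
    assert est.by_length["estimate"].iloc[0] == pytest.approx(0.5)
    # degenerate weight: all mass on area 1
    W1 = W.copy()
    W1["W"] = np.where(W1["area"] == 1, 1.0, 0.0)
    est1 = combine_weighted(area, W1)
    assert est1.by_length["estimate"].iloc[0] == pytest.approx(0.2)
    assert est1.by_length["variance"].iloc[0] == pytest.approx(0.01)


def test_combine_matches_bruteforce_summation():
    rng = np.random.default_rng(0)
    mids = tuple(np.arange(48.0, 109.0, 5.0))
    p_hats = rng.uniform(0, 1, 3)
    var_ps = rng.uniform(0.001, 0.02, 3)
    area = _area_frame(p_hats, var_ps, mids=mids)
    N, p, f = _tables(
        rng.uniform(0.5, 3, 3), rng.uniform(0.1, 1, 3), rng.uniform(0.1, 1, 3),
        mids=mids,
    )
    W = compute_weights(N, p, f)
    est = combine_weighted(area, W)
    merged = area.merge(W, on=["length_class_mid", "area", "season"])
    for _, row in est.by_length.iterrows():
        cell = merged[merged["length_class_mid"] == row["length_class_mid"]]
        P = float((cell["W"] * cell["p_hat"]).sum())
        V = float((cell["W"] ** 2 * cell["var_p"]).sum())
        assert row["estimate"] == pytest.approx(P, abs=1e-12)
        assert row["variance"] == pytest.approx(V, abs=1e-12)
        assert cell["p_hat"].min() - 1e-12 <= row["estimate"] <= cell["p_hat"].max() + 1e-12


def test_combine_requires_variance_where_weighted():
    area = _area_frame([0.2, 0.8], [0.01, np.nan])
    N, p, f = _tables([1.0, 1.0], [0.5, 0.5], [0.5, 0.5])
    with pytest.raises(ValueError, match="missing variance"):
        combine_weighted(area, compute_weights(N, p, f))


def test_reduced_variance_matches_monte_carlo():
    """Var(sum W p_hat) = sum W^2 Var(p_hat) against resampling the area
    estimates from their sampling distributions (weights held fixed)."""
    rng = np.random.default_rng(1)
    p_hats = np.array([0.3, 0.55, 0.8])
    sds = np.array([0.03, 0.05, 0.02])
    W = np.array([0.5, 0.3, 0.2])
    draws = rng.normal(p_hats, sds, size=(10_000, 3)) @ W
    mc_var = draws.var(ddof=1)
    formula = float(np.sum(W**2 * sds**2))
    assert abs(formula - mc_var) / mc_var < 0.10


def test_area_season_ogives_structure_and_ordering():
    params = PopulationParams(n_sets=600, fish_per_set_mean=30, seed=6)
    pop = simulate_population(params)
    fem = pop[pop["sampled"] & (pop["sex"] == "F")]
    tab, fit = area_season_ogives(fem)
    assert set(tab["area"]) == {1, 2, 3}
    assert set(tab["season"]) == {1, 2}
    assert tab["p_hat"].between(0, 1).all()
    assert (tab["var_p"] >= 0).all()
    # northern band mature at smaller length in the spawning season
    s1 = tab[(tab["season"] == 1) & (tab["length_class_mid"] == 83.0)]
    assert (
        s1.loc[s1["area"] == 1, "p_hat"].iloc[0]
        > s1.loc[s1["area"] == 3, "p_hat"].iloc[0]
    )


def test_area_season_ogives_requires_all_strata():
    params = PopulationParams(n_sets=200, seed=7)
    pop = simulate_population(params)
    fem = pop[pop["sex"] == "F"]
    northless = fem[fem["latitude_degS"] > 23]
    with pytest.raises(ValueError, match="band 1"):
        area_season_ogives(northless)


def test_unweighted_ogive_monotone_and_seasonal():
    params = PopulationParams(n_sets=400, fish_per_set_mean=30, seed=9)
    pop = simulate_population(params)
    fem = pop[pop["sampled"] & (pop["sex"] == "F")]
    uw = fit_unweighted(fem, 2)
    grid = np.linspace(60, 105, 46)
    vals = uw.predict(grid)
    assert np.all(np.diff(vals) > 0)
    lo, hi = uw.l50_ci()
    assert lo <= uw.l50 <= hi
    with pytest.raises(ValueError, match="no records"):
        fit_unweighted(fem[fem["month"] == 1], 2)


def _ogive_frame(mids, estimates, season=1):
    return pd.DataFrame(
        {"length_class_mid": mids, "season": season, "estimate": estimates}
    )


def test_length_at_quantile_interpolation():
    frame = _ogive_frame([85.0, 90.0], [0.4, 0.6])
    assert length_at_quantile(frame, 0.5, season=1) == pytest.approx(87.5)


def test_length_at_quantile_step_on_dense_grid():
    mids = np.arange(70.0, 100.0, 0.01)
    frame = _ogive_frame(mids, (mids >= 87.0).astype(float))
    assert length_at_quantile(frame, 0.5, season=1) == pytest.approx(87.0, abs=0.02)


def test_length_at_full_maturity_threshold():
    mids = [80.0, 85.0, 90.0, 95.0]
    frame = _ogive_frame(mids, [0.5, 0.9, 0.992, 0.999])
    assert length_at_quantile(frame, 1.0, season=1) == 90.0
    assert np.isnan(length_at_quantile(_ogive_frame(mids, [0.1, 0.2, 0.3, 0.4]), 0.5, season=1))
    with pytest.raises(ValueError, match="q must be"):
        length_at_quantile(frame, 0.0, season=1)
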