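"""Penalized-spline engine: transforms, VIF, fits, ranking, CV, contrasts."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoscape.gam import (
    PenalizedGAM,
    SmoothTerm,
    TensorTerm,
    TruncationBounds,
    compare_periods,
    cross_validate,
    effect_class,
    inverse_transform,
    rank_models,
    transform_response,
    truncate_covariates,
    vif,
)
from benthoscape.validation import binomial_recovery, smooth_recovery


# -- truncation and transform ----------------------------------------------

def test_truncation_clamps_and_is_idempotent():
    t = pd.DataFrame(
        {"distance_km": [0.5, 2.0, 5.0], "depth_m": [4.0, 12.0, 20.0],
         "other": [1, 2, 3]}
    )
    out = truncate_covariates(t)
    assert out["distance_km"].tolist() == [0.75, 2.0, 4.0]
    assert out["depth_m"].tolist() == [6.0, 12.0, 18.0]
    assert out["other"].tolist() == [1, 2, 3]
    pd.testing.assert_frame_equal(truncate_covariates(out), out)


def test_truncation_bounds_validate():
    with pytest.raises(ValueError):
        TruncationBounds(distance=(4.0, 0.75))


def test_transform_response_known_values():
    assert transform_response(0.0) == pytest.approx(np.log(0.5))
    assert transform_response(0.5) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        transform_response(-0.1)


@settings(deadline=None)
@given(st.floats(0, 1e6))
def test_transform_round_trip(x):
    assert inverse_transform(transform_response(x)) == pytest.approx(
        x, rel=1e-12, abs=1e-9
    )


# -- VIF --------------------------------------------------------------------

def test_vif_orthogonal_covariates_are_one():
    n = 64
    x1 = np.tile([1.0, -1.0], n // 2)
    x2 = np.repeat([1.0, -1.0], n // 2)
    out = vif(pd.DataFrame({"a": x1, "b": x2}))
    np.testing.assert_allclose(out["vif"], 1.0, atol=1e-10)
    assert not out["flagged"].any()


def test_vif_matches_closed_form_at_correlation_09():
    # construct two vectors with sample correlation exactly 0.9
    n = 200
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    z1 = np.sqrt(2) * np.cos(t)
    z2 = np.sqrt(2) * np.sin(t)
    x2 = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
    out = vif(pd.DataFrame({"a": z1, "b": x2}))
    np.testing.assert_allclose(out["vif"], 1 / (1 - 0.81), rtol=1e-9)
    assert not out["flagged"].any()


def test_vif_flags_near_duplicate_columns(rng):
    x = rng.normal(size=100)
    out = vif(pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-6, 100)}))
    assert out["flagged"].all()
    exact = vif(pd.DataFrame({"a": x, "b": 2 * x}))
    assert np.isinf(exact["vif"]).all() and exact["flagged"].all()


# -- fitting ----------------------------------------------------------------

def test_constant_response_gives_null_fit(rng):
    X = pd.DataFrame({"x": rng.uniform(0, 1, 100)})
    m = PenalizedGAM(smooth_terms=[SmoothTerm("x")]).fit(X, np.full(100, 3.0))
    assert m.deviance_explained_ == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(m.fitted_response_, 3.0, atol=1e-8)


def test_sin_curve_recovery():
    assert smooth_recovery(n=500, seed=0)["rmse"] <= 0.1


def test_binomial_linear_predictor_recovery():
    assert binomial_recovery(n=1000, seed=0)["correlation"] >= 0.9


def test_large_penalty_limit_is_linear_fit(rng):
    x = rng.uniform(0, 1, 200)
    y = 1.0 + 2.0 * x + rng.normal(0, 0.1, 200)
    X = pd.DataFrame({"x": x})
    m = PenalizedGAM(smooth_terms=[SmoothTerm("x", k=10, order=2)]).fit(
        X, y, fix_smoothing=[12.0]
    )
    b, a = np.polyfit(x, y, 1)
    rmse = np.sqrt(np.mean((m.fitted_response_ - (a + b * x)) ** 2))
    assert rmse < 1e-3


def test_gaussian_fit_reconstructs_response_exactly(hurdle_table):
    pos = hurdle_table[hurdle_table["biomass_g_m2"] > 0]
    y = transform_response(pos["biomass_g_m2"].to_numpy())
    m = PenalizedGAM(
        smooth_terms=[SmoothTerm("northing_km")],
        factor="period",
        random_intercept="station_id",
    ).fit(pos, y)
    np.testing.assert_allclose(m.fitted_response_ + m.residuals_, y, atol=1e-10)


def test_binomial_probabilities_strictly_inside_unit_interval(hurdle_table):
    y = (hurdle_table["biomass_g_m2"] > 0).astype(float)
    m = PenalizedGAM(
        family="binomial", smooth_terms=[SmoothTerm("northing_km")],
        factor="period",
    ).fit(hurdle_table, y)
    assert (m.fitted_response_ > 0).all() and (m.fitted_response_ < 1).all()


def test_nested_model_does_not_lose_deviance(rng):
    x = rng.uniform(0, 1, 300)
    z = rng.uniform(0, 1, 300)
    y = np.sin(2 * np.pi * x) + 0.5 * z + rng.normal(0, 0.2, 300)
    X = pd.DataFrame({"x": x, "z": z})
    small = PenalizedGAM(smooth_terms=[SmoothTerm("x")]).fit(
        X, y, fix_smoothing=[0.0]
    )
    big = PenalizedGAM(
        smooth_terms=[SmoothTerm("x"), SmoothTerm("z")]
    ).fit(X, y, fix_smoothing=[0.0, 0.0])
    assert big.deviance_explained_ >= small.deviance_explained_ - 1e-10


def test_distance_and_depth_cannot_cooccur(hurdle_table):
    m = PenalizedGAM(
        smooth_terms=[SmoothTerm("distance_km"), SmoothTerm("depth_m")]
    )
    with pytest.raises(ValueError, match="collinear"):
        m.fit(hurdle_table, hurdle_table["biomass_g_m2"].to_numpy())


def test_insufficient_unique_values_raise(rng):
    X = pd.DataFrame({"x": np.repeat([0.0, 0.5, 1.0], 20)})
    with pytest.raises(ValueError, match="unique"):
        PenalizedGAM(smooth_terms=[SmoothTerm("x", k=10)]).fit(
            X, rng.normal(size=60)
        )


def test_matches_independent_gam_implementation(rng):
    """Cross-check the engine against statsmodels' penalized GAM on a
    1-D Gaussian smooth: the two fitted curves should agree closely."""
    from statsmodels.gam.api import BSplines, GLMGam

    x = rng.uniform(0, 1, 400)
    truth = np.sin(2 * np.pi * x)
    y = truth + rng.normal(0, 0.25, 400)
    ours = PenalizedGAM(smooth_terms=[SmoothTerm("x", k=12)]).fit(
        pd.DataFrame({"x": x}), y
    )
    bs = BSplines(x[:, None], df=[12], degree=[3])
    fits = [
        GLMGam(y, np.ones((len(y), 1)), smoother=bs, alpha=[a]).fit()
        for a in np.logspace(-4, 4, 9)
    ]
    ref = min(fits, key=lambda r: r.aic)
    rmse = np.sqrt(np.mean((ours.fitted_response_ - ref.fittedvalues) ** 2))
    assert rmse < 0.1


# -- ranking and effect sizes ----------------------------------------------

def _stub_fit(aic, edf=5.0, dev=0.3, y_hash="h"):
    return SimpleNamespace(
        aic_=aic, edf_=edf, deviance_explained_=dev, _y_hash_=y_hash
    )


def test_rank_models_delta_classes():
    out = rank_models({"a": _stub_fit(100.0), "b": _stub_fit(101.5)})
    assert set(out["class"]) == {"equivalent"}
    assert sorted(out["delta_aic"]) == [0.0, 1.5]
    out = rank_models({"a": _stub_fit(100.0), "b": _stub_fit(112.0)})
    assert out.set_index("model")["class"]["b"] == "poor"
    out = rank_models({"a": _stub_fit(100.0), "b": _stub_fit(105.0),
                       "c": _stub_fit(108.5)})
    assert out.set_index("model")["class"]["b"] == "less-information"
    assert out.set_index("model")["class"]["c"] == "indeterminate"
    single = rank_models({"only": _stub_fit(50.0)})
    assert single["delta_aic"].iloc[0] == 0.0 and single["selected"].iloc[0]


def test_rank_models_parsimony_tie_break():
    out = rank_models(
        {"complex": _stub_fit(100.0, edf=12.0), "simple": _stub_fit(101.0, edf=4.0)}
    )
    assert out.loc[out["selected"], "model"].iloc[0] == "simple"


def test_rank_models_rejects_mixed_responses():
    with pytest.raises(ValueError, match="different"):
        rank_models({"a": _stub_fit(1.0, y_hash="x"), "b": _stub_fit(2.0, y_hash="y")})


@pytest.mark.parametrize(
    "dev,expected",
    [(0.53, "large"), (0.40, "large"), (0.30, "medium"), (0.23, "medium"),
     (0.16, "small"), (0.04, "small"), (0.039, "none"), (0.0, "none")],
)
def test_effect_class_thresholds(dev, expected):
    assert effect_class(dev) == expected


@settings(deadline=None)
@given(st.floats(0, 1), st.floats(0, 1))
def test_effect_class_is_monotone(a, b):
    order = ["none", "small", "medium", "large"]
    lo, hi = sorted([a, b])
    assert order.index(effect_class(lo)) <= order.index(effect_class(hi))


# -- cross-validation and contrasts ----------------------------------------

def test_cross_validation_reports_consistent_d_pct(hurdle_table):
    y = transform_response(hurdle_table["biomass_g_m2"].to_numpy())
    m = PenalizedGAM(
        smooth_terms=[SmoothTerm("northing_km")], factor="period",
        random_intercept="station_id", optimizer_maxfev=40,
    ).fit(hurdle_table, y)
    cv = cross_validate(m, hurdle_table, y, folds=4, seed=0)
    assert cv["d_pct"] == pytest.approx(
        100 * (cv["xv"] - cv["gs"]) / cv["gs"]
    )
    assert len(np.unique(cv["fold_assignment"])) == 4
    # replicates of one station stay in one fold
    df = pd.DataFrame({"st": hurdle_table["station_id"],
                       "fold": cv["fold_assignment"]})
    assert (df.groupby("st")["fold"].nunique() == 1).all()


def test_cv_error_exceeds_in_sample_error_in_most_replicates():
    from benthoscape.synthetic import (
        GroupSimConfig, GPConfig, ShelfDomainConfig, generate_stations,
        simulate_group,
    )

    worse = 0
    n_reps = 20
    for s in range(n_reps):
        skel = generate_stations(
            ShelfDomainConfig(n_stations=15, periods=("P1", "P2"), seed=100 + s)
        )
        g = GroupSimConfig(
            group="g",
            occupancy_logit={"const": 50.0},
            conditional_logmean={"const": 1.0, "northing_km": 0.05},
            residual_gp=GPConfig(partial_sill=0.0, nugget=0.0),
            obs_noise_sd=0.5,
        )
        t = simulate_group(skel, g, seed=100 + s)
        y = transform_response(t["biomass_g_m2"].to_numpy())
        m = PenalizedGAM(
            smooth_terms=[SmoothTerm("northing_km")], factor="period",
            optimizer_maxfev=30,
        ).fit(t, y)
        cv = cross_validate(m, t, y, folds=4, seed=s)
        if cv["xv"] >= cv["gs"]:
            worse += 1
    assert worse >= 0.8 * n_reps


def _period_sim(offsets, noise, seed=0, n_st=40):
    rng = np.random.default_rng(seed)
    st_ids = np.repeat([f"S{i}" for i in range(n_st)], 3 * len(offsets))
    periods = np.tile(np.repeat(list(offsets), 3), n_st)
    x = np.repeat(rng.uniform(0, 1, n_st), 3 * len(offsets))
    y = np.array([offsets[p] for p in periods]) + 0.3 * x
    if noise:
        y = y + rng.normal(0, noise, len(y))
    X = pd.DataFrame({"northing_km": x, "period": periods, "station_id": st_ids})
    return X, y


def test_period_contrasts_recover_planted_ordering():
    X, y = _period_sim({"P1": 0.0, "P2": 2.0, "P3": -2.0}, noise=0.1)
    m = PenalizedGAM(
        smooth_terms=[SmoothTerm("northing_km")], factor="period",
    ).fit(X, y)
    out = compare_periods(m)
    assert out["ordering"] == "P3 < P1 < P2"
    assert out["contrasts"]["significant"].all()


def test_period_contrasts_null_case_and_two_levels():
    X, y = _period_sim({"P1": 0.0, "P2": 0.0, "P3": 0.0}, noise=0.5, seed=3)
    m = PenalizedGAM(factor="period",
                     smooth_terms=[SmoothTerm("northing_km")]).fit(X, y)
    out = compare_periods(m)
    assert not out["contrasts"]["significant"].any()
    X2, y2 = _period_sim({"P1": 0.0, "P2": 1.0}, noise=0.1)
    m2 = PenalizedGAM(factor="period",
                      smooth_terms=[SmoothTerm("northing_km")]).fit(X2, y2)
    assert len(compare_periods(m2)["contrasts"]) == 1
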