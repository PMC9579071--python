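"""Variography, kriging, grids and the regression-kriging composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthoscape.gam import PenalizedGAM, SmoothTerm, inverse_transform
from benthoscape.geostat import (
    AnisotropyScaling,
    EmpiricalVariogram,
    KrigingInterpolator,
    PredictionGrid,
    VariogramModel,
    aggregate_blocks,
    empirical_variogram,
    fit_variogram,
    inverse_transform_coords,
    jitter_duplicates,
    krige,
    make_grid,
    read_ascii_grid,
    regression_krige,
    transform_coords,
    write_ascii_grid,
)
from benthoscape.validation import kriging_exactness, variogram_recovery


# -- coordinates ------------------------------------------------------------

def test_transform_coords_default_factors():
    u, v = transform_coords(1.0, 5_860_000.0)
    assert (u, v) == (10_000.0, 5_860.0)
    assert transform_coords(0.0, 0.0) == (0.0, 0.0)


@settings(deadline=None)
@given(st.floats(0.01, 10), st.floats(1e5, 1e7))
def test_transform_coords_round_trip(d, n):
    u, v = transform_coords(d, n)
    d2, n2 = inverse_transform_coords(u, v)
    assert d2 == pytest.approx(d, rel=1e-12)
    assert n2 == pytest.approx(n, rel=1e-12)


def test_jitter_leaves_distinct_points_alone(rng):
    c = rng.uniform(0, 10, (30, 2))
    np.testing.assert_array_equal(jitter_duplicates(c, 0.5, seed=1), c)


def test_jitter_separates_duplicates_within_amplitude():
    c = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
    out = jitter_duplicates(c, 0.5, seed=7)
    assert len(np.unique(out, axis=0)) == 3
    disp = np.hypot(*(out - c).T)
    assert disp.max() <= 0.5 + 1e-12
    np.testing.assert_array_equal(
        out, jitter_duplicates(c, 0.5, seed=7)
    )  # seeded determinism


# -- empirical variogram ----------------------------------------------------

def test_empirical_variogram_constant_field_is_zero(rng):
    c = rng.uniform(0, 10, (40, 2))
    emp = empirical_variogram(np.full(40, 2.5), c)
    np.testing.assert_allclose(emp.gamma, 0.0, atol=1e-20)


def test_empirical_variogram_two_point_hand_calculation():
    emp = empirical_variogram(
        [0.0, 2.0], [[0.0, 0.0], [1.0, 0.0]], n_bins=1, max_lag=2.0
    )
    assert emp.gamma.tolist() == [2.0]  # (2-0)^2 / 2
    assert emp.counts.tolist() == [1]


def test_empirical_variogram_white_noise_is_flat(rng):
    c = rng.uniform(0, 50, (500, 2))
    z = rng.normal(0, 1, 500)
    emp = empirical_variogram(z, c)
    se = 1.0 / np.sqrt(emp.counts / 2)
    assert (np.abs(emp.gamma - 1.0) < 3 * se + 0.05).all()


def test_empirical_variogram_guards():
    with pytest.raises(ValueError, match="coincident"):
        empirical_variogram([1.0, 2.0], [[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        empirical_variogram([1.0], [[0, 0]])


# -- variogram models and fitting ------------------------------------------

def test_variogram_models_limits_and_monotonicity():
    for fam in ("exponential", "spherical"):
        vm = VariogramModel(fam, 0.2, 1.0, 4.0)
        h = np.linspace(0, 20, 200)
        g = vm(h)
        assert np.all(np.diff(g) >= -1e-12)
        assert g[0] == pytest.approx(vm.nugget)
        assert g[-1] == pytest.approx(vm.sill, rel=1e-2)
    sph = VariogramModel("spherical", 0.1, 1.0, 5.0)
    assert sph(5.0) == pytest.approx(sph.sill, rel=1e-12)  # sill exactly at range
    with pytest.raises(ValueError):
        VariogramModel("gaussian", 0, 1, 1)


@pytest.mark.parametrize("family", ["exponential", "spherical"])
def test_fit_variogram_self_consistency(family):
    truth = VariogramModel(family, 0.1, 1.0, 5.0)
    lags = np.linspace(0.5, 20, 10)
    emp = EmpiricalVariogram(lags, truth(lags), np.full(10, 100))
    fit = fit_variogram(emp, family)
    assert fit.nugget == pytest.approx(0.1, abs=1e-3)
    assert fit.partial_sill == pytest.approx(1.0, abs=1e-3)
    assert fit.range_ == pytest.approx(5.0, abs=1e-3)


def test_fit_variogram_pure_nugget_limit():
    lags = np.linspace(1, 10, 8)
    emp = EmpiricalVariogram(lags, np.full(8, 0.7), np.full(8, 50))
    fit = fit_variogram(emp, "exponential")
    assert fit.partial_sill + fit.nugget == pytest.approx(0.7, abs=1e-3)
    assert fit.partial_sill < 0.05


def test_variogram_recovery_from_simulated_fields():
    out = variogram_recovery(n_stations=200, n_seeds=5, seed=1)
    assert out["median_rel_error_range"] <= 0.35
    assert out["median_rel_error_sill"] <= 0.35


# -- kriging ----------------------------------------------------------------

def test_kriging_is_exact_with_zero_nugget():
    out = kriging_exactness(n=50, seed=0)
    assert out["max_abs_error_at_data"] < 1e-8
    assert out["max_variance_at_data"] < 1e-8
    assert out["max_weight_sum_deviation"] < 1e-10


def test_two_point_simple_kriging_matches_hand_solution():
    vm = VariogramModel("exponential", 0.1, 1.0, 5.0)
    coords = np.array([[0.0, 0.0], [3.0, 0.0]])
    z = np.array([1.0, 2.0])
    target = np.array([[1.0, 0.0]])
    k_mat = vm.covariance(np.array([[0.0, 3.0], [3.0, 0.0]]))
    k_mat[np.diag_indices(2)] += vm.nugget
    k0 = vm.covariance(np.array([1.0, 2.0]))
    w = np.linalg.solve(k_mat, k0)
    pred, var = krige(z, coords, target, vm)
    assert pred[0] == pytest.approx(w @ z, abs=1e-10)
    assert var[0] == pytest.approx(vm.sill - w @ k0, abs=1e-10)


def test_kriging_far_field_limits(rng):
    vm = VariogramModel("exponential", 0.1, 1.0, 5.0)
    c = rng.uniform(0, 20, (30, 2))
    z = rng.normal(0, 1, 30)
    pred, var = krige(z, c, np.array([[500.0, 500.0]]), vm)
    assert pred[0] == pytest.approx(0.0, abs=1e-6)
    assert var[0] == pytest.approx(vm.sill, rel=1e-6)


def test_kriging_variance_nonnegative_and_singular_guard(rng):
    vm = VariogramModel("exponential", 0.0, 1.0, 5.0)
    c = rng.uniform(0, 10, (25, 2))
    z = rng.normal(size=25)
    est = KrigingInterpolator(variogram=vm, kind="ordinary").fit(c, z)
    _, var = est.predict(rng.uniform(0, 10, (40, 2)), return_variance=True)
    assert (var >= 0).all()
    dup = np.vstack([c, c[:1]])
    with pytest.raises(np.linalg.LinAlgError, match="near-duplicate"):
        KrigingInterpolator(variogram=vm).fit(dup, np.r_[z, z[:1]])


# -- grids ------------------------------------------------------------------

def test_aggregate_blocks_arithmetic():
    g = PredictionGrid(0.0, 0.0, 500.0, 2, 2,
                       values=np.array([[1.0, 2.0], [3.0, 4.0]]))
    b = aggregate_blocks(g, 1000.0)
    assert b.values.shape == (1, 1)
    assert b.values[0, 0] == pytest.approx(2.5)


def test_aggregate_blocks_constant_and_partial_masks():
    g = make_grid((0, 2000), (0, 1000), 250.0)
    g.values = np.full((g.ny, g.nx), 7.0)
    b = aggregate_blocks(g, 1000.0)
    assert np.allclose(b.values[b.mask], 7.0)
    g.mask[:, :2] = False
    g.values[:, 0] = 1e9  # masked cells must not contribute
    b2 = aggregate_blocks(g, 1000.0)
    assert np.allclose(b2.values[b2.mask], 7.0)
    g.mask[:] = False
    b3 = aggregate_blocks(g, 1000.0)
    assert not b3.mask.any()


def test_block_mean_between_member_extremes(rng):
    g = make_grid((0, 3000), (0, 2000), 100.0)
    g.values = rng.uniform(0, 10, (g.ny, g.nx))
    b = aggregate_blocks(g, 1000.0)
    assert (b.values[b.mask] >= g.values.min()).all()
    assert (b.values[b.mask] <= g.values.max()).all()


def test_ascii_grid_round_trip(tmp_path, rng):
    g = make_grid((0, 500), (0, 300), 100.0)
    g.values = rng.uniform(0, 5, (g.ny, g.nx))
    g.mask[0, 0] = False
    p = tmp_path / "g.asc"
    write_ascii_grid(g, p)
    back = read_ascii_grid(p)
    assert back.nx == g.nx and back.ny == g.ny
    np.testing.assert_allclose(
        back.values[g.mask], g.values[g.mask], atol=1e-6
    )
    assert not back.mask[0, 0]


# -- regression kriging -----------------------------------------------------

def test_regression_krige_zero_residuals_returns_regression_surface(rng):
    """A constant response fits exactly, so the kriged-residual field is
    zero and the surface equals the back-transformed regression trend."""
    n = 60
    X = pd.DataFrame(
        {
            "distance_km": rng.uniform(1, 3, n),
            "northing_m": rng.uniform(5.85e6, 5.86e6, n),
            "period": "P1",
        }
    )
    X["northing_km"] = X["northing_m"] / 1000.0
    y = np.full(n, 1.3)
    m = PenalizedGAM(smooth_terms=[SmoothTerm("northing_km")]).fit(X, y)
    grid = make_grid((1000, 3000), (5.85e6, 5.852e6), 500.0)
    xx, yy = grid.cell_centers()
    gridcov = pd.DataFrame(
        {"distance_km": xx.ravel() / 1000.0, "northing_m": yy.ravel(),
         "northing_km": yy.ravel() / 1000.0, "period": "P1"}
    )
    surf = regression_krige(m, X, grid, gridcov, seed=0)
    np.testing.assert_allclose(
        surf.values, np.exp(1.3) - 0.5, rtol=1e-6
    )


def test_regression_krige_hurdle_compositions_run_and_bound(hurdle_table):
    from benthoscape.hurdle import fit_hurdle
    from benthoscape.gam import TensorTerm

    h = fit_hurdle(
        hurdle_table, hurdle_table["biomass_g_m2"].to_numpy(),
        tensor_terms=[TensorTerm(("northing_km", "distance_km"))],
        factor="period", optimizer_maxfev=30,
    )
    grid = make_grid((1000, 3000), (5.846e6, 5.850e6), 500.0)
    xx, yy = grid.cell_centers()
    gridcov = pd.DataFrame(
        {"distance_km": xx.ravel() / 1000.0, "northing_m": yy.ravel(),
         "northing_km": yy.ravel() / 1000.0, "period": "P1"}
    )
    for comp in ("literal", "full_product"):
        surf = regression_krige(
            h, hurdle_table, grid, gridcov, composition=comp, seed=0
        )
        assert np.isfinite(surf.values[surf.mask]).all()
        assert (surf.values[surf.mask] >= 0).all()
    with pytest.raises(ValueError, match="composition"):
        regression_krige(h, hurdle_table, grid, gridcov, composition="bogus")
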