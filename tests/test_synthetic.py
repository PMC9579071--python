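"""Synthetic shelf generator: design structure, determinism, GP field."""

import numpy as np
import pandas as pd
import pytest

from benthoscape.geostat import empirical_variogram, transform_coords
from benthoscape.synthetic import (
    GPConfig,
    GroupSimConfig,
    ShelfDomainConfig,
    generate_stations,
    read_sample_table,
    simulate_group,
    write_sample_table,
)


@pytest.mark.parametrize(
    "n_stations,reps,periods,expected_rows",
    [
        (223, 3, ("P1",), 669),
        (1, 1, ("P1",), 1),
        (10, 3, ("P1", "P2", "P3"), 90),
    ],
)
def test_generate_stations_row_counts(n_stations, reps, periods, expected_rows):
    cfg = ShelfDomainConfig(
        n_stations=n_stations, replicates_per_station=reps, periods=periods,
        seed=1,
    )
    assert len(generate_stations(cfg)) == expected_rows


def test_depth_is_exact_linear_map_without_noise():
    cfg = ShelfDomainConfig(
        n_stations=30, depth_model=(4.0, 3.0, 0.0), seed=2
    )
    t = generate_stations(cfg)
    np.testing.assert_allclose(
        t["depth_m"], 4.0 + 3.0 * t["distance_km"], rtol=1e-12
    )


def test_generate_stations_zones_and_invariants():
    cfg = ShelfDomainConfig(n_stations=60, seed=4)
    t = generate_stations(cfg)
    assert set(t["zone"]) <= {"South", "Middle", "North"}
    assert (t["depth_m"] > 0).all()
    lo, hi = cfg.distance_range
    assert t["distance_km"].between(lo, hi).all()
    # zone must be monotone in northing
    z = t.groupby("zone")["northing_m"]
    assert z.max()["South"] < z.min()["Middle"] < z.max()["Middle"] < z.min()["North"]


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        ShelfDomainConfig(n_stations=0)
    with pytest.raises(ValueError):
        ShelfDomainConfig(distance_range=(0.0, 3.0))
    with pytest.raises(ValueError):
        ShelfDomainConfig(zone_breaks=(5.0, 4.0))
    with pytest.raises(ValueError):
        GroupSimConfig(group="g", target_zero_fraction=1.0)
    with pytest.raises(ValueError):
        GPConfig(range_=0.0)


def test_fixed_seed_reproduces_tables(skeleton_small):
    cfg = ShelfDomainConfig(n_stations=15, seed=9)
    pd.testing.assert_frame_equal(
        generate_stations(cfg), generate_stations(cfg)
    )
    g = GroupSimConfig(group="g", target_zero_fraction=0.2)
    a = simulate_group(skeleton_small, g, seed=11)
    b = simulate_group(skeleton_small, g, seed=11)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_group(skeleton_small, g, seed=12)
    assert not a["biomass_g_m2"].equals(c["biomass_g_m2"])


def test_degenerate_noise_gives_exact_backtransform(skeleton_small):
    g = GroupSimConfig(
        group="g",
        occupancy_logit={"const": 50.0},
        conditional_logmean={"const": 1.5},
        residual_gp=GPConfig(partial_sill=0.0, nugget=0.0),
        obs_noise_sd=0.0,
    )
    t = simulate_group(skeleton_small, g, seed=1)
    np.testing.assert_allclose(
        t["biomass_g_m2"], np.exp(1.5) - 0.5, rtol=1e-12
    )


def test_achieved_zero_fraction_matches_binomial_oracle():
    # constant occupancy p = 0.5 over 2000 rows
    cfg = ShelfDomainConfig(n_stations=2000, replicates_per_station=1,
                            periods=("P1",), seed=6)
    skel = generate_stations(cfg)
    g = GroupSimConfig(
        group="g",
        occupancy_logit={"const": 0.0},
        residual_gp=GPConfig(partial_sill=0.0, nugget=0.0),
    )
    t = simulate_group(skel, g, seed=3)
    zfrac = (t["biomass_g_m2"] == 0).mean()
    se = np.sqrt(0.25 / 2000)
    assert abs(zfrac - 0.5) < 3 * se


def test_target_zero_fraction_calibration(skeleton_small):
    g = GroupSimConfig(
        group="g",
        occupancy_logit={"northing_km": 0.5},
        residual_gp=GPConfig(partial_sill=0.0, nugget=0.0),
        target_zero_fraction=0.3,
    )
    reps = [
        (simulate_group(skeleton_small, g, seed=s)["biomass_g_m2"] == 0).mean()
        for s in range(5)
    ]
    assert abs(np.mean(reps) - 0.3) < 0.07


def test_station_field_has_configured_spatial_structure():
    """Station effects drawn from an exponential GP show low semivariance
    at lags well below the range (closed form gamma(h) = sill(1-e^(-h/r)))."""
    # compress the cross-shore span so working lags probe h << range
    cfg = ShelfDomainConfig(
        n_stations=150, replicates_per_station=1, periods=("P1",),
        distance_range=(1.0, 1.0004),
        northing_extent=(5_850_000.0, 5_850_020.0),
        seed=8,
    )
    skel = generate_stations(cfg)
    g = GroupSimConfig(
        group="g",
        occupancy_logit={"const": 50.0},
        conditional_logmean={"const": 0.0},
        residual_gp=GPConfig("exponential", partial_sill=1.0, range_=5.0,
                             nugget=0.0),
        obs_noise_sd=0.0,
    )
    t = simulate_group(skel, g, seed=2)
    effects = np.log(t["biomass_g_m2"].to_numpy() + 0.5)
    u, v = transform_coords(
        t["distance_km"].to_numpy(), t["northing_m"].to_numpy()
    )
    emp = empirical_variogram(effects, np.column_stack([u, v]), n_bins=10,
                              max_lag=5.0)
    short = emp.gamma[emp.lags < 1.0]
    assert short.size > 0 and short.mean() < 0.5


def test_write_read_round_trip(tmp_path, hurdle_table):
    p = tmp_path / "t.csv"
    write_sample_table(hurdle_table, p, ["seed=5 stage=test"])
    back = read_sample_table(p)
    pd.testing.assert_frame_equal(
        back, hurdle_table.reset_index(drop=True), check_like=True
    )
    lines = p.read_text().splitlines()
    assert lines[0].startswith("#")
    assert len(lines) == 2 + len(hurdle_table)  # comment + header + rows


def test_write_empty_table_is_header_only(tmp_path):
    p = tmp_path / "e.csv"
    write_sample_table(
        pd.DataFrame(columns=["station_id", "biomass_g_m2"]), p
    )
    lines = p.read_text().splitlines()
    assert lines == ["station_id,biomass_g_m2"]
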