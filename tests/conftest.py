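import numpy as np
import pandas as pd
import pytest

from benthoscape.synthetic import (
    GPConfig,
    GroupSimConfig,
    ShelfDomainConfig,
    generate_stations,
    simulate_group,
)


@pytest.fixture(scope="session")
def skeleton_small() -> pd.DataFrame:
    """20 stations x 3 replicates x 3 periods."""
    return generate_stations(
        ShelfDomainConfig(
            n_stations=20,
            northing_extent=(5_846_000.0, 5_856_000.0),
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def hurdle_table(skeleton_small) -> pd.DataFrame:
    """Simulated group with ~30% zeros and smooth structure."""
    g = GroupSimConfig(
        group="SimGroup",
        occupancy_logit={"northing_km": 0.3},
        conditional_logmean={
            "const": 2.0,
            "gauss(northing_km,5851,3)": 0.8,
            "distance_km": -0.3,
            "period:P3": -0.4,
        },
        residual_gp=GPConfig("exponential", 0.1, 1000.0, 0.0),
        obs_noise_sd=0.5,
        target_zero_fraction=0.30,
    )
    return simulate_group(skeleton_small, g, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
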