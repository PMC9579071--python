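"""Seeded synthetic station tables for a nearshore benthic sampling design.

The generator emulates the statistical structure of an intensive grab-sample
survey on a narrow sandy shelf: ~200 stations sampled with three replicate
grabs in each of three summer periods, alongshore zones (South/Middle/North),
distance-to-shore between roughly 0.9 and 3.6 km, water depth increasing
with distance from shore, group-specific zero inflation, lognormal
conditional biomass with smooth alongshore/cross-shore structure, and an
anisotropic exponential spatial random field shared by the replicates of a
station.

Surfaces (occupancy logits and conditional log-means) are declared as small
coefficient dictionaries, e.g.::

    {"const": 3.0, "northing_km": -0.05, "sin(northing_km/8)": 0.6,
     "gauss(distance_km,1.5,0.6)": 1.0, "period:P3": -0.5}

which keeps generator configurations serialisable in plain text configs.
"""

from __future__ import annotations

import io
import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ShelfDomainConfig",
    "GPConfig",
    "GroupSimConfig",
    "eval_surface",
    "generate_stations",
    "simulate_group",
    "write_sample_table",
    "read_sample_table",
    "SAMPLE_COLUMNS",
]

SAMPLE_COLUMNS = [
    "station_id",
    "replicate_id",
    "period",
    "zone",
    "northing_m",
    "distance_km",
    "depth_m",
    "group",
    "biomass_g_m2",
]

#: working-coordinate factors: cross-shore km -> decimeters, northing m -> km
CROSS_SHORE_FACTOR = 1e4
ALONGSHORE_FACTOR = 1e-3


@dataclass(frozen=True)
class ShelfDomainConfig:
    """Sampling-design configuration for the synthetic shelf.

    Defaults reproduce the study conditions of the emulated survey: 223
    stations x 3 replicates x 3 periods, distance to shore 0.86-3.56 km and
    depth increasing roughly linearly from ~6.7 m to ~16.1 m across that
    range, with alongshore zone terciles.
    """

    n_stations: int = 223
    replicates_per_station: int = 3
    northing_extent: tuple[float, float] = (5_840_000.0, 5_862_000.0)
    distance_range: tuple[float, float] = (0.86, 3.56)
    #: (intercept m, slope m/km, noise sd m) for depth as f(distance)
    depth_model: tuple[float, float, float] = (3.7, 3.5, 0.6)
    periods: tuple[str, ...] = ("P1", "P2", "P3")
    zone_breaks: tuple[float, ...] | None = None
    #: if < 1, each period revisits only this fraction of stations
    period_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.replicates_per_station < 1:
            raise ValueError("station and replicate counts must be >= 1")
        lo, hi = self.distance_range
        if not (0 < lo < hi <= 10):
            raise ValueError("distance_range must lie within (0, 10] km")
        if self.zone_breaks is not None and not np.all(
            np.diff(self.zone_breaks) > 0
        ):
            raise ValueError("zone_breaks must be strictly increasing")
        if not (0 < self.period_fraction <= 1):
            raise ValueError("period_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GPConfig:
    """Residual Gaussian-process model in anisotropy-corrected coordinates."""

    family: str = "exponential"
    partial_sill: float = 0.4
    range_: float = 5.0
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.partial_sill < 0 or self.nugget < 0 or self.range_ <= 0:
            raise ValueError("require partial_sill,nugget >= 0 and range > 0")
        if self.family not in ("exponential", "spherical"):
            raise ValueError(f"unknown GP family {self.family!r}")


@dataclass(frozen=True)
class GroupSimConfig:
    """Generative hurdle configuration for one prey group."""

    group: str
    occupancy_logit: dict = field(default_factory=lambda: {"const": 5.0})
    conditional_logmean: dict = field(default_factory=lambda: {"const": 3.0})
    residual_gp: GPConfig = GPConfig()
    obs_noise_sd: float = 0.5
    #: if set, the occupancy intercept is calibrated so that the expected
    #: absence fraction equals this value
    target_zero_fraction: float | None = None

    def __post_init__(self) -> None:
        z = self.target_zero_fraction
        if z is not None and not (0 <= z < 1):
            raise ValueError("target_zero_fraction must be in [0, 1)")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be >= 0")


_TERM_RE = re.compile(
    r"^(?:(?P<const>const)"
    r"|sin\((?P<sincol>\w+)/(?P<wavelen>[-\d.eE]+)\)"
    r"|gauss\((?P<gcol>\w+),(?P<center>[-\d.eE]+),(?P<scale>[-\d.eE]+)\)"
    r"|period:(?P<period>\w+)"
    r"|(?P<col>\w+))$"
)


def eval_surface(coefs: dict, table: pd.DataFrame) -> np.ndarray:
    """Evaluate a coefficient-dictionary surface on a station table.

    Supported term keys: ``const``, a covariate column name (linear),
    ``sin(col/wavelength)``, ``gauss(col,center,scale)`` and
    ``period:LABEL`` (additive offset for rows of that period).
    """
    out = np.zeros(len(table), dtype=float)
    for key, coef in coefs.items():
        m = _TERM_RE.match(key.replace(" ", ""))
        if m is None:
            raise KeyError(f"unparseable surface term {key!r}")
        if m.group("const"):
            out += coef
        elif m.group("sincol"):
            x = table[m.group("sincol")].to_numpy(dtype=float)
            out += coef * np.sin(2 * np.pi * x / float(m.group("wavelen")))
        elif m.group("gcol"):
            x = table[m.group("gcol")].to_numpy(dtype=float)
            c, s = float(m.group("center")), float(m.group("scale"))
            out += coef * np.exp(-0.5 * ((x - c) / s) ** 2)
        elif m.group("period"):
            out += coef * (
                table["period"].to_numpy() == m.group("period")
            ).astype(float)
        else:
            out += coef * table[m.group("col")].to_numpy(dtype=float)
    return out


def generate_stations(cfg: ShelfDomainConfig) -> pd.DataFrame:
    """Generate the station/replicate/period skeleton of a sample table.

    Station coordinates are drawn once and shared across periods; depth is a
    linear function of distance-to-shore plus Gaussian noise, clipped to stay
    strictly positive.  Zones are assigned from northing via ``zone_breaks``
    (terciles of the northing extent by default).  Deterministic for a fixed
    ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    n = cfg.n_stations
    northing = rng.uniform(*cfg.northing_extent, size=n)
    distance = rng.uniform(*cfg.distance_range, size=n)
    a, b, sd = cfg.depth_model
    depth = a + b * distance + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    depth = np.maximum(depth, 0.1)

    if cfg.zone_breaks is None:
        lo, hi = cfg.northing_extent
        breaks = (lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3)
    else:
        breaks = cfg.zone_breaks
    zone = np.select(
        [northing < breaks[0], northing < breaks[-1]],
        ["South", "Middle"],
        default="North",
    )

    rows = []
    for period in cfg.periods:
        if cfg.period_fraction < 1.0:
            k = max(1, int(round(cfg.period_fraction * n)))
            idx = np.sort(rng.choice(n, size=k, replace=False))
        else:
            idx = np.arange(n)
        for i in idx:
            for r in range(1, cfg.replicates_per_station + 1):
                rows.append(
                    (
                        f"S{i + 1:04d}",
                        r,
                        period,
                        zone[i],
                        northing[i],
                        distance[i],
                        depth[i],
                    )
                )
    t = pd.DataFrame(
        rows,
        columns=[
            "station_id",
            "replicate_id",
            "period",
            "zone",
            "northing_m",
            "distance_km",
            "depth_m",
        ],
    )
    t["northing_km"] = t["northing_m"] / 1000.0
    return t


def _gp_correlation(h: np.ndarray, gp: GPConfig) -> np.ndarray:
    hr = h / gp.range_
    if gp.family == "exponential":
        return np.exp(-hr)
    c = 1.0 - 1.5 * hr + 0.5 * hr**3
    return np.where(h < gp.range_, c, 0.0)


def _station_field(
    coords_u: np.ndarray, coords_v: np.ndarray, gp: GPConfig, rng
) -> np.ndarray:
    """Draw one correlated station-level field from the configured GP."""
    n = coords_u.size
    if gp.partial_sill == 0 and gp.nugget == 0:
        return np.zeros(n)
    du = coords_u[:, None] - coords_u[None, :]
    dv = coords_v[:, None] - coords_v[None, :]
    h = np.hypot(du, dv)
    cov = gp.partial_sill * _gp_correlation(h, gp)
    cov[np.diag_indices(n)] += gp.nugget
    scale = max(gp.partial_sill + gp.nugget, 1e-12)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            chol = np.linalg.cholesky(cov + jitter * scale * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        i, j = np.unravel_index(
            np.argmin(h + np.eye(n) * np.inf), h.shape
        )
        raise np.linalg.LinAlgError(
            "station covariance not positive definite after jitter; "
            f"closest station pair: indices ({i}, {j}) at lag {h[i, j]:.3g}"
        )
    return chol @ rng.standard_normal(n)


def _calibrate_intercept(lp: np.ndarray, target_zero: float) -> float:
    """Shift c such that mean(sigmoid(lp + c)) == 1 - target_zero."""
    from scipy.optimize import brentq

    def f(c):
        return np.mean(1.0 / (1.0 + np.exp(-(lp + c)))) - (1.0 - target_zero)

    if target_zero == 0.0:
        return 40.0  # occupancy prob ~ 1 everywhere
    return brentq(f, -60.0, 60.0, xtol=1e-10)


def simulate_group(
    skeleton: pd.DataFrame, g: GroupSimConfig, seed: int = 0
) -> pd.DataFrame:
    """Simulate one prey group's biomass on a station skeleton.

    Presence is Bernoulli with logit given by ``g.occupancy_logit`` (the
    intercept recalibrated when ``target_zero_fraction`` is set); for
    present rows ``ln(X + 0.5)`` is the conditional log-mean surface plus a
    station-level spatial field plus replicate noise, back-transformed as
    ``exp(.) - 0.5`` and clipped at zero.  The spatial field is drawn once
    per station in anisotropy-corrected working coordinates (cross-shore
    decimeters, alongshore kilometers) so replicates of a station share it.
    """
    t = skeleton.copy()
    if "northing_km" not in t.columns:
        t["northing_km"] = t["northing_m"] / 1000.0
    rng = np.random.default_rng([seed, zlib.crc32(g.group.encode()), 7])

    lp = eval_surface(g.occupancy_logit, t)
    if g.target_zero_fraction is not None:
        lp = lp - lp.mean()  # keep only the shape; level is calibrated
        lp = lp + _calibrate_intercept(lp, g.target_zero_fraction)
    p = 1.0 / (1.0 + np.exp(-lp))
    present = rng.random(len(t)) < p

    stations = t.drop_duplicates("station_id").set_index("station_id")
    u = stations["distance_km"].to_numpy() * CROSS_SHORE_FACTOR
    v = stations["northing_m"].to_numpy() * ALONGSHORE_FACTOR
    field = _station_field(u, v, g.residual_gp, rng)
    gp_by_station = pd.Series(field, index=stations.index)

    ln_y = (
        eval_surface(g.conditional_logmean, t)
        + gp_by_station.reindex(t["station_id"]).to_numpy()
        + rng.normal(0.0, g.obs_noise_sd, size=len(t))
    )
    biomass = np.where(present, np.maximum(np.exp(ln_y) - 0.5, 0.0), 0.0)

    out = t.copy()
    out["group"] = g.group
    out["biomass_g_m2"] = biomass
    return out


def write_sample_table(
    t: pd.DataFrame, path, header_comments: list[str] | None = None
) -> None:
    """Write a sample table as CSV with optional '#' provenance lines."""
    buf = io.StringIO()
    for line in header_comments or []:
        buf.write(f"# {line}\n")
    cols = [c for c in SAMPLE_COLUMNS if c in t.columns] + [
        c for c in t.columns if c not in SAMPLE_COLUMNS
    ]
    t[cols].to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_sample_table(path) -> pd.DataFrame:
    """Read a CSV sample table, skipping '#' provenance lines."""
    return pd.read_csv(path, comment="#")
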