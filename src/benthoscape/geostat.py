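"""Anisotropy-corrected variography and regression kriging.

On a narrow shelf, spatial correlation is much stronger alongshore than
across the depth gradient.  Geographic coordinates are therefore rescaled
into working units before any distance computation — distance-to-shore in
decimeters (km x 1e4) and northing in kilometers (m x 1e-3) — so that one
working unit of separation carries comparable correlation in either
direction.  Regression residuals are kriged in these working coordinates
(exponential or spherical variogram, Cressie-weighted WLS fit), added back
to the regression surface on a regular prediction grid (20-m spacing by
default), and block-averaged to 1 km^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .gam import PenalizedGAM, inverse_transform
from .hurdle import HurdleGAM

__all__ = [
    "AnisotropyScaling",
    "transform_coords",
    "inverse_transform_coords",
    "jitter_duplicates",
    "EmpiricalVariogram",
    "empirical_variogram",
    "VariogramModel",
    "fit_variogram",
    "KrigingInterpolator",
    "krige",
    "PredictionGrid",
    "BlockGrid",
    "make_grid",
    "regression_krige",
    "aggregate_blocks",
    "write_ascii_grid",
    "read_ascii_grid",
]


@dataclass(frozen=True)
class AnisotropyScaling:
    """Working-coordinate factors correcting geometric anisotropy.

    ``cross_shore`` maps distance-to-shore km to working units (default
    1e4, i.e. decimeters); ``alongshore`` maps northing m to working units
    (default 1e-3, i.e. kilometers).
    """

    cross_shore: float = 1e4
    alongshore: float = 1e-3

    def __post_init__(self):
        if self.cross_shore <= 0 or self.alongshore <= 0:
            raise ValueError("scaling factors must be positive")


def transform_coords(
    distance_km, northing_m, s: AnisotropyScaling = AnisotropyScaling()
):
    """Map (distance km, northing m) to anisotropy-corrected (u, v)."""
    u = np.asarray(distance_km, dtype=float) * s.cross_shore
    v = np.asarray(northing_m, dtype=float) * s.alongshore
    return u, v


def inverse_transform_coords(
    u, v, s: AnisotropyScaling = AnisotropyScaling()
):
    """Invert :func:`transform_coords`."""
    return np.asarray(u, float) / s.cross_shore, np.asarray(v, float) / s.alongshore


def jitter_duplicates(
    coords: np.ndarray, amplitude: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Break exactly coincident coordinate pairs by a small seeded offset.

    Only rows that collide with an earlier row are moved; each displacement
    has Euclidean norm at most ``amplitude``.  Distinct inputs are returned
    unchanged.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    c = np.array(coords, dtype=float)
    rng = np.random.default_rng([seed, 23])
    for _ in range(100):
        _, first = np.unique(c, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(len(c)), first)
        if dup.size == 0:
            return c
        r = amplitude * np.sqrt(rng.uniform(0.25, 1.0, size=dup.size))
        theta = rng.uniform(0, 2 * np.pi, size=dup.size)
        c[dup, 0] += r * np.cos(theta)
        c[dup, 1] += r * np.sin(theta)
    raise RuntimeError("could not separate coincident points")


# --------------------------------------------------------------------------
# variograms
# --------------------------------------------------------------------------

@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariance estimate."""

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray


def empirical_variogram(
    values, coords, n_bins: int = 15, max_lag: float | None = None
) -> EmpiricalVariogram:
    """Matheron semivariance in equal-width lag bins.

    gamma_hat(h) = (1 / 2N(h)) * sum over pairs in bin h of (z_i - z_j)^2.
    ``max_lag`` defaults to half the maximum pairwise distance; bins with
    no pairs are dropped.
    """
    z = np.asarray(values, dtype=float)
    c = np.asarray(coords, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 points")
    iu, ju = np.triu_indices(len(z), k=1)
    h = np.hypot(c[iu, 0] - c[ju, 0], c[iu, 1] - c[ju, 1])
    if np.all(h == 0):
        raise ValueError("all points coincident; jitter coordinates first")
    if max_lag is None:
        max_lag = 0.5 * float(h.max())
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    sq = 0.5 * (z[iu] - z[ju]) ** 2
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(h, edges) - 1
    keep = (which >= 0) & (which < n_bins)
    lags, gammas, counts = [], [], []
    for b in range(n_bins):
        m = keep & (which == b)
        n_pairs = int(np.count_nonzero(m))
        if n_pairs == 0:
            continue
        lags.append(float(h[m].mean()))
        gammas.append(float(sq[m].mean()))
        counts.append(n_pairs)
    return EmpiricalVariogram(
        np.asarray(lags), np.asarray(gammas), np.asarray(counts)
    )


@dataclass(frozen=True)
class VariogramModel:
    """Parametric variogram: nugget + partial sill + range.

    Exponential: gamma(h) = nugget + psill * (1 - exp(-h/range));
    spherical: gamma(h) = nugget + psill * (1.5 h/r - 0.5 (h/r)^3) for
    h <= r, reaching the full sill exactly at h = r.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self):
        if self.family not in ("exponential", "spherical"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("require nugget,psill >= 0 and range > 0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + self.partial_sill * (1.0 - self.correlation(h))

    def correlation(self, h) -> np.ndarray:
        """Correlation of the structured (non-nugget) component."""
        h = np.asarray(h, dtype=float)
        hr = h / self.range_
        if self.family == "exponential":
            return np.exp(-hr)
        c = 1.0 - 1.5 * hr + 0.5 * hr**3
        return np.where(h < self.range_, c, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Covariance of the structured component (no nugget)."""
        return self.partial_sill * self.correlation(h)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def fit_variogram(
    e: EmpiricalVariogram, family: str = "exponential"
) -> VariogramModel:
    """Cressie-weighted WLS fit of a variogram model.

    Minimizes sum of N(h) * (gamma_model(h)/gamma_emp... ) — concretely the
    residual sqrt(N(h)) * (gamma_model - gamma_hat) / gamma_model, the
    standard weighted least squares criterion with weights N(h) /
    gamma_model(h)^2, under non-negativity constraints.
    """
    if e.lags.size < 3:
        raise ValueError("need at least 3 retained lag bins")
    g = e.gamma
    floor = max(1e-10, 1e-4 * float(np.mean(g) + 1e-12))
    nug0 = max(float(g[0]) * 0.5, 0.0)
    psill0 = max(float(np.max(g)) - nug0, floor)
    rng0 = max(float(e.lags[-1]) / 3.0, 1e-6)

    def resid(theta):
        nug, psill, r = theta
        model = VariogramModel(family, max(nug, 0.0), max(psill, 0.0), max(r, 1e-9))
        gm = np.maximum(model(e.lags), floor)
        return np.sqrt(e.counts) * (gm - g) / gm

    res = least_squares(
        resid,
        x0=[nug0, psill0, rng0],
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    if not res.success and res.cost > 1e-6 * len(g):
        raise RuntimeError(
            f"variogram WLS did not converge; best candidate {res.x} "
            f"with objective {res.cost:.6g}"
        )
    nug, psill, r = res.x
    return VariogramModel(family, float(nug), float(psill), float(r))


# --------------------------------------------------------------------------
# kriging
# --------------------------------------------------------------------------

class KrigingInterpolator(BaseEstimator):
    """Simple or ordinary kriging in working coordinates.

    Parameters
    ----------
    variogram : VariogramModel, optional
        Fixed variogram; if None, one is fitted by WLS at ``fit`` time.
    family : str
        Variogram family used when fitting internally.
    kind : {"simple", "ordinary"}
        Simple kriging assumes a known mean (``mean``, default 0 — the
        natural choice for regression residuals); ordinary kriging enforces
        weights summing to 1.
    """

    def __init__(
        self,
        variogram: VariogramModel | None = None,
        family: str = "exponential",
        kind: str = "simple",
        mean: float = 0.0,
        n_bins: int = 15,
        max_lag: float | None = None,
        chunk_size: int = 2000,
    ):
        self.variogram = variogram
        self.family = family
        self.kind = kind
        self.mean = mean
        self.n_bins = n_bins
        self.max_lag = max_lag
        self.chunk_size = chunk_size

    def fit(self, coords: np.ndarray, values):
        if self.kind not in ("simple", "ordinary"):
            raise ValueError(f"unknown kriging kind {self.kind!r}")
        c = np.asarray(coords, dtype=float)
        z = np.asarray(values, dtype=float)
        vg = self.variogram
        if vg is None:
            vg = fit_variogram(
                empirical_variogram(z, c, self.n_bins, self.max_lag),
                self.family,
            )
        self.variogram_ = vg
        if vg.nugget <= 0:
            _, first, counts = np.unique(
                c, axis=0, return_index=True, return_counts=True
            )
            if (counts > 1).any():
                i = int(first[np.argmax(counts > 1)])
                raise np.linalg.LinAlgError(
                    "singular kriging system; near-duplicate points share "
                    f"the coordinates of index {i} — jitter first"
                )
        d = _pairwise(c, c)
        cov = vg.covariance(d)
        cov[np.diag_indices(len(z))] += vg.nugget
        scale = max(vg.sill, 1e-12)
        for jitter in (0.0, 1e-10, 1e-8):
            try:
                self._chol_ = cho_factor(cov + jitter * scale * np.eye(len(z)))
                break
            except np.linalg.LinAlgError:
                continue
        else:
            off = d + np.eye(len(z)) * np.inf
            i, j = np.unravel_index(np.argmin(off), off.shape)
            raise np.linalg.LinAlgError(
                "singular kriging system; near-duplicate points at indices "
                f"({i}, {j}), working distance {d[i, j]:.3g} — jitter first"
            )
        self._coords_ = c
        self._z_ = z
        if self.kind == "ordinary":
            ones = np.ones(len(z))
            self._ci1_ = cho_solve(self._chol_, ones)
        return self

    def predict(
        self, targets: np.ndarray, return_variance: bool = False,
        return_weights: bool = False,
    ):
        """Kriging predictions (and variances) at target coordinates.

        Processes targets in chunks so large grids stay within memory.
        """
        t = np.atleast_2d(np.asarray(targets, dtype=float))
        vg = self.variogram_
        preds = np.empty(len(t))
        var = np.empty(len(t)) if return_variance else None
        wts = np.empty((len(t), len(self._z_))) if return_weights else None
        resid_mean = self._z_ - (self.mean if self.kind == "simple" else 0.0)
        for start in range(0, len(t), self.chunk_size):
            sl = slice(start, min(start + self.chunk_size, len(t)))
            d = _pairwise(t[sl], self._coords_)
            k0 = vg.covariance(d.T)  # (n_data, n_chunk)
            w = cho_solve(self._chol_, k0)
            if self.kind == "simple":
                preds[sl] = self.mean + w.T @ resid_mean
                if return_variance:
                    var[sl] = vg.sill - np.sum(w * k0, axis=0)
            else:
                mu = (1.0 - self._ci1_ @ k0) / (self._ci1_ @ np.ones(len(self._z_)))
                w = w + np.outer(self._ci1_, mu)
                preds[sl] = w.T @ self._z_
                if return_variance:
                    var[sl] = vg.sill - np.sum(w * k0, axis=0) - mu
            if return_weights:
                wts[sl] = w.T
        if return_variance:
            var = np.maximum(var, 0.0)
        out = [preds]
        if return_variance:
            out.append(var)
        if return_weights:
            out.append(wts)
        return preds if len(out) == 1 else tuple(out)


def krige(
    values,
    coords,
    targets,
    v: VariogramModel,
    kind: str = "simple",
    return_variance: bool = True,
):
    """Functional one-shot kriging (see :class:`KrigingInterpolator`)."""
    est = KrigingInterpolator(variogram=v, kind=kind).fit(coords, values)
    return est.predict(targets, return_variance=return_variance)


def _pairwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist

    return cdist(a, b)


# --------------------------------------------------------------------------
# grids
# --------------------------------------------------------------------------

@dataclass
class PredictionGrid:
    """Regular prediction grid in physical coordinates.

    ``x`` is cross-shore meters (distance-to-shore x 1000), ``y`` is
    northing meters; ``values``/``variance`` are (ny, nx) arrays indexed
    [row=y, col=x]; masked (False) cells are outside the supported domain.
    """

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int
    values: np.ndarray | None = None
    variance: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.cell_size <= 0 or self.nx < 1 or self.ny < 1:
            raise ValueError("invalid grid geometry")
        if self.mask is None:
            self.mask = np.ones((self.ny, self.nx), dtype=bool)

    def cell_centers(self):
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def to_table(self) -> pd.DataFrame:
        xx, yy = self.cell_centers()
        t = pd.DataFrame(
            {
                "x_m": xx.ravel(),
                "y_m": yy.ravel(),
                "value": (self.values.ravel() if self.values is not None
                          else np.nan),
                "variance": (self.variance.ravel() if self.variance is not None
                             else np.nan),
                "masked": ~self.mask.ravel(),
            }
        )
        return t


@dataclass
class BlockGrid:
    """1-km^2-style block means of a finer prediction grid."""

    x0: float
    y0: float
    block_size: float
    nx: int
    ny: int
    values: np.ndarray = None
    mask: np.ndarray = None


def make_grid(
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    cell_size: float = 20.0,
) -> PredictionGrid:
    """Build an empty grid covering the ranges at the given spacing (m)."""
    nx = max(1, int(np.ceil((x_range[1] - x_range[0]) / cell_size)))
    ny = max(1, int(np.ceil((y_range[1] - y_range[0]) / cell_size)))
    return PredictionGrid(x_range[0], y_range[0], cell_size, nx, ny)


def aggregate_blocks(
    grid: PredictionGrid, block_size: float = 1000.0
) -> BlockGrid:
    """Average grid cells into square blocks (1 km^2 by default).

    Partial edge blocks use the cells available; blocks with no unmasked
    cell are masked.
    """
    if grid.values is None:
        raise ValueError("grid has no values to aggregate")
    r = block_size / grid.cell_size
    nbx = int(np.ceil(grid.nx / r))
    nby = int(np.ceil(grid.ny / r))
    vals = np.full((nby, nbx), np.nan)
    mask = np.zeros((nby, nbx), dtype=bool)
    col_of = (np.arange(grid.nx) * grid.cell_size // block_size).astype(int)
    row_of = (np.arange(grid.ny) * grid.cell_size // block_size).astype(int)
    for by in range(nby):
        rows = row_of == by
        for bx in range(nbx):
            cols = col_of == bx
            sub = grid.values[np.ix_(rows, cols)]
            ok = grid.mask[np.ix_(rows, cols)] & np.isfinite(sub)
            if ok.any():
                vals[by, bx] = float(sub[ok].mean())
                mask[by, bx] = True
    return BlockGrid(grid.x0, grid.y0, block_size, nbx, nby, vals, mask)


# --------------------------------------------------------------------------
# regression kriging
# --------------------------------------------------------------------------

def _working_coords(
    distance_km, northing_m, s: AnisotropyScaling
) -> np.ndarray:
    u, v = transform_coords(distance_km, northing_m, s)
    return np.column_stack([u, v])


def _grid_working_coords(
    grid: PredictionGrid, s: AnisotropyScaling
) -> np.ndarray:
    xx, yy = grid.cell_centers()
    return _working_coords(xx.ravel() / 1000.0, yy.ravel(), s)


def _krige_residuals(
    resid, X, grid, s, family, kind, jitter_amplitude, seed,
    variogram=None, n_bins=15,
):
    coords = _working_coords(
        X["distance_km"].to_numpy(), X["northing_m"].to_numpy(), s
    )
    coords = jitter_duplicates(coords, jitter_amplitude, seed)
    est = KrigingInterpolator(
        variogram=variogram, family=family, kind=kind, n_bins=n_bins
    ).fit(coords, np.asarray(resid, float))
    pred, var = est.predict(
        _grid_working_coords(grid, s), return_variance=True
    )
    shape = (grid.ny, grid.nx)
    return pred.reshape(shape), var.reshape(shape), est.variogram_


def regression_krige(
    model,
    X: pd.DataFrame,
    grid: PredictionGrid,
    grid_covariates: pd.DataFrame,
    anisotropy: AnisotropyScaling = AnisotropyScaling(),
    family: str = "exponential",
    occupancy_family: str | None = None,
    composition: str = "literal",
    kind: str = "simple",
    jitter_amplitude: float = 0.5,
    seed: int = 0,
    transform_offset: float = 0.5,
) -> PredictionGrid:
    """Regression-kriging surface for a fitted model on a prediction grid.

    The trend surface is the model's population-level prediction at the
    grid covariates; residuals (response-scale, against the population
    prediction at the data rows) are kriged in working coordinates and the
    two are combined:

    * Gaussian model — cells are exp(trend + kriged residual) - offset on
      the transformed scale, clipped at 0;
    * logistic model — probability + kriged 0/1 residual, clipped to [0,1];
    * hurdle model — default "literal" composition: the unconditional
      regression surface (p_hat x back-transformed conditional) plus the
      product of the occupancy and conditional kriged-residual surfaces,
      clipped at 0; the alternative "full_product" composition multiplies
      the two full regression+kriging surfaces instead.

    ``grid_covariates`` must hold one row per grid cell (row-major) with
    the model covariates, already truncated to the regression support.
    """
    shape = (grid.ny, grid.nx)
    out = PredictionGrid(
        grid.x0, grid.y0, grid.cell_size, grid.nx, grid.ny,
        mask=grid.mask.copy(),
    )
    if len(grid_covariates) != grid.nx * grid.ny:
        raise ValueError("grid_covariates must have one row per grid cell")

    if isinstance(model, HurdleGAM):
        occ = model.occupancy_
        con = model.conditional_
        occ_fam = occupancy_family or family
        y01 = occ._y_
        occ_resid = y01 - occ.predict(X, type="response")
        pos = np.asarray(y01, bool)
        con_resid = con._y_ - con.predict(X[pos])
        kr_p, var_p, vg_p = _krige_residuals(
            occ_resid, X, grid, anisotropy, occ_fam, kind,
            jitter_amplitude, seed,
        )
        kr_c, var_c, vg_c = _krige_residuals(
            con_resid, X[pos], grid, anisotropy, family, kind,
            jitter_amplitude, seed + 1,
        )
        p_hat = occ.predict(grid_covariates, type="response").reshape(shape)
        cond_bt = inverse_transform(
            con.predict(grid_covariates), transform_offset, clip=True
        ).reshape(shape)
        if composition == "literal":
            vals = np.maximum(p_hat * cond_bt + kr_p * kr_c, 0.0)
        elif composition == "full_product":
            p_full = np.clip(p_hat + kr_p, 0.0, 1.0)
            c_full = inverse_transform(
                con.predict(grid_covariates).reshape(shape) + kr_c,
                transform_offset,
                clip=True,
            )
            vals = np.maximum(p_full * c_full, 0.0)
        else:
            raise ValueError(f"unknown composition {composition!r}")
        out.values = vals
        out.variance = var_c
        out.variograms_ = {"occupancy": vg_p, "conditional": vg_c}
    elif isinstance(model, PenalizedGAM) and model.family == "binomial":
        occ_fam = occupancy_family or family
        resid = model._y_ - model.predict(X, type="response")
        kr, var, vg = _krige_residuals(
            resid, X, grid, anisotropy, occ_fam, kind, jitter_amplitude, seed
        )
        p_hat = model.predict(grid_covariates, type="response").reshape(shape)
        out.values = np.clip(p_hat + kr, 0.0, 1.0)
        out.variance = var
        out.variograms_ = {"occupancy": vg}
    elif isinstance(model, PenalizedGAM):
        resid = model._y_ - model.predict(X)
        kr, var, vg = _krige_residuals(
            resid, X, grid, anisotropy, family, kind, jitter_amplitude, seed
        )
        trend = model.predict(grid_covariates).reshape(shape)
        out.values = inverse_transform(
            trend + kr, transform_offset, clip=True
        )
        out.variance = var
        out.variograms_ = {"conditional": vg}
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    out.values = np.where(out.mask, out.values, np.nan)
    return out


# --------------------------------------------------------------------------
# ESRI ASCII grid I/O
# --------------------------------------------------------------------------

def write_ascii_grid(grid: PredictionGrid, path, nodata: float = -9999.0):
    """Write values as an ESRI ASCII grid (.asc)."""
    vals = np.where(
        grid.mask & np.isfinite(grid.values), grid.values, nodata
    )
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.nx}\n")
        fh.write(f"nrows {grid.ny}\n")
        fh.write(f"xllcorner {grid.x0:.6f}\n")
        fh.write(f"yllcorner {grid.y0:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:.6f}\n")
        for row in vals[::-1]:  # ASCII grids run top-down
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> PredictionGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = header["nodata_value"]
    mask = data != nodata
    values = np.where(mask, data, np.nan)
    return PredictionGrid(
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
        int(header["ncols"]),
        int(header["nrows"]),
        values=values,
        mask=mask,
    )
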