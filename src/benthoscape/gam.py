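"""Penalized-spline additive regression with mixed-model extras.

The engine fits Gaussian (on ln(X+0.5)-transformed energy) and binomial
(presence/absence) additive models by penalized least squares / penalized
IRLS.  Model structure follows common practice for benthic survey data:

* a fixed sampling-period factor,
* cubic P-spline smooths of alongshore northing (km), distance to shore
  (km) or water depth (m) — distance and depth are collinear on a shelf and
  are never allowed in the same model,
* tensor-product interaction smooths (2- or 3-way, optionally with period
  as a by-factor), one penalty per margin,
* a station random intercept, implemented as a ridge-penalized indicator
  block whose penalty maps to the variance component.

Smoothing parameters are chosen by generalized cross-validation (GCV); the
criterion name is recorded on the fit so an alternative can be swapped in.
Model comparison uses AIC with effective degrees of freedom (trace of the
influence matrix) and the usual rule-of-thumb ΔAIC classes; effect sizes
are read off the proportion of deviance explained against percent-variance
benchmarks (small 0.04, medium 0.23, large 0.40).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._basis import (
    MarginalBasis,
    difference_penalty,
    tensor_design,
    tensor_penalties,
)

__all__ = [
    "SmoothTerm",
    "TensorTerm",
    "TruncationBounds",
    "EffectSizeCriteria",
    "PenalizedGAM",
    "truncate_covariates",
    "transform_response",
    "inverse_transform",
    "vif",
    "rank_models",
    "effect_class",
    "cross_validate",
    "compare_periods",
]


# --------------------------------------------------------------------------
# term and configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothTerm:
    """1-D penalized cubic spline smooth of a covariate."""

    cov: str
    k: int = 10
    order: int = 2


@dataclass(frozen=True)
class TensorTerm:
    """Tensor-product interaction smooth over 2 or 3 covariates.

    ``by`` names a factor column; the smooth is then replicated per factor
    level (a varying-coefficient interaction), sharing one smoothing
    parameter per margin across levels.
    """

    covs: tuple[str, ...]
    k: int = 5
    order: int = 2
    by: str | None = None

    def __post_init__(self):
        if not 2 <= len(self.covs) <= 3:
            raise ValueError("tensor terms take 2 or 3 covariates")


@dataclass(frozen=True)
class TruncationBounds:
    """Clamping bounds applied to covariates before regression/prediction."""

    distance: tuple[float, float] = (0.75, 4.0)
    depth: tuple[float, float] = (6.0, 18.0)

    def __post_init__(self):
        for lo, hi in (self.distance, self.depth):
            if not lo < hi:
                raise ValueError("truncation bounds must satisfy lower < upper")


@dataclass(frozen=True)
class EffectSizeCriteria:
    """Percent-variance benchmarks (Cohen's f 0.2 / 0.5 / 0.8)."""

    small: float = 0.04
    medium: float = 0.23
    large: float = 0.40

    def __post_init__(self):
        if not self.small < self.medium < self.large:
            raise ValueError("effect-size thresholds must be increasing")


# --------------------------------------------------------------------------
# simple operations
# --------------------------------------------------------------------------

def truncate_covariates(
    t: pd.DataFrame, bounds: TruncationBounds = TruncationBounds()
) -> pd.DataFrame:
    """Clamp distance-to-shore and depth into the regression support.

    Idempotent; returns a copy with only the two covariate columns altered.
    """
    out = t.copy()
    if "distance_km" in out.columns:
        out["distance_km"] = out["distance_km"].clip(*bounds.distance)
    if "depth_m" in out.columns:
        out["depth_m"] = out["depth_m"].clip(*bounds.depth)
    return out


def transform_response(energy, offset: float = 0.5):
    """ln(X + offset) transform of a non-negative energy density."""
    e = np.asarray(energy, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy must be non-negative")
    out = np.log(e + offset)
    return float(out) if out.ndim == 0 else out


def inverse_transform(y, offset: float = 0.5, clip: bool = False):
    """Inverse of :func:`transform_response`: exp(y) - offset."""
    out = np.exp(np.asarray(y, dtype=float)) - offset
    if clip:
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def vif(covariates: pd.DataFrame, threshold: float = 7.0) -> pd.DataFrame:
    """Variance inflation factors with a flag at the screening threshold.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression (with intercept) of
    covariate j on the remaining covariates; perfect collinearity is
    reported as infinite and flagged.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two covariates")
    x = covariates.to_numpy(dtype=float)
    n = x.shape[0]
    if n <= len(cols):
        raise ValueError("need more rows than covariates")
    rows = []
    for j, name in enumerate(cols):
        yj = x[:, j]
        others = np.c_[np.ones(n), np.delete(x, j, axis=1)]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": name, "vif": v, "flagged": v > threshold})
    return pd.DataFrame(rows)


def effect_class(
    deviance_explained: float, c: EffectSizeCriteria = EffectSizeCriteria()
) -> str:
    """Map a proportion of deviance explained to an effect-size class."""
    d = float(deviance_explained)
    if not 0.0 <= d <= 1.0:
        raise ValueError("deviance explained must be in [0, 1]")
    if d >= c.large:
        return "large"
    if d >= c.medium:
        return "medium"
    if d >= c.small:
        return "small"
    return "none"


def rank_models(fits: dict[str, "PenalizedGAM"]) -> pd.DataFrame:
    """ΔAIC ranking of fits of the same response.

    Classes follow the usual rule of thumb: ≤2 equivalent, 3–7 carries less
    information, >10 poor, in between indeterminate.  Among models with
    ΔAIC ≤ 2 the one with fewest effective degrees of freedom is marked
    ``selected`` (parsimony tie-break).
    """
    if not fits:
        raise ValueError("no fits to rank")
    hashes = {f._y_hash_ for f in fits.values()}
    if len(hashes) > 1:
        raise ValueError("fits were made on different responses/data")
    rows = [
        {"model": name, "aic": f.aic_, "edf": f.edf_, "dev_expl": f.deviance_explained_}
        for name, f in fits.items()
    ]
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    out["class"] = out["delta_aic"].map(_delta_aic_class)
    eligible = out[out["delta_aic"] <= 2.0]
    sel = eligible.sort_values(["edf", "delta_aic"]).index[0]
    out["selected"] = False
    out.loc[sel, "selected"] = True
    return out.sort_values("delta_aic").reset_index(drop=True)


def _delta_aic_class(d: float) -> str:
    if d <= 2.0:
        return "equivalent"
    if 3.0 <= d <= 7.0:
        return "less-information"
    if d > 10.0:
        return "poor"
    return "indeterminate"


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

class PenalizedGAM(BaseEstimator):
    """Penalized-spline additive model with a station random intercept.

    Parameters
    ----------
    family : {"gaussian", "binomial"}
        Gaussian fits are penalized least squares on the (already
        transformed) response; binomial fits use penalized IRLS on a 0/1
        response with a logit link.
    smooth_terms : sequence of SmoothTerm
    tensor_terms : sequence of TensorTerm
    factor : str, optional
        Name of an unpenalized categorical fixed effect (sampling period).
    random_intercept : str, optional
        Column of grouping labels (station ids) for a ridge-penalized
        random intercept.
    criterion : str
        Smoothing-parameter selection criterion; only "gcv" is implemented,
        recorded on the fit as ``criterion_``.
    optimizer_maxfev : int
        Budget for the Nelder–Mead search over log smoothing parameters.

    Attributes (after fit)
    ----------------------
    coef_, edf_, aic_, deviance_explained_, gcv_, smoothing_params_,
    random_intercept_var_, fitted_link_, fitted_response_, residuals_
    (response-scale), scale_ (Gaussian residual variance estimate).
    """

    def __init__(
        self,
        family: str = "gaussian",
        smooth_terms=(),
        tensor_terms=(),
        factor: str | None = None,
        random_intercept: str | None = None,
        criterion: str = "gcv",
        max_pirls: int = 100,
        tol: float = 1e-8,
        optimizer_maxfev: int = 150,
    ):
        self.family = family
        self.smooth_terms = tuple(smooth_terms)
        self.tensor_terms = tuple(tensor_terms)
        self.factor = factor
        self.random_intercept = random_intercept
        self.criterion = criterion
        self.max_pirls = max_pirls
        self.tol = tol
        self.optimizer_maxfev = optimizer_maxfev

    # -- design construction ------------------------------------------------

    def _validate_terms(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        covs = [t.cov for t in self.smooth_terms]
        for t in self.tensor_terms:
            covs.extend(t.covs)
        if "distance_km" in covs and "depth_m" in covs:
            raise ValueError(
                "distance_km and depth_m are collinear on the shelf and "
                "may not appear in the same model"
            )

    def _build_training_design(self, X: pd.DataFrame):
        n = len(X)
        cols = [np.ones((n, 1))]
        penalties = []  # (slice, matrix) in full design coords
        meta = {"factor_levels": None, "terms": [], "ri_levels": None}
        pos = 1

        if self.factor is not None:
            levels = sorted(pd.unique(X[self.factor]))
            if len(levels) < 2:
                raise ValueError(
                    f"factor {self.factor!r} needs >= 2 levels, got {levels}"
                )
            meta["factor_levels"] = levels
            d = _factor_dummies(X[self.factor], levels)
            meta["factor_slice"] = slice(pos, pos + d.shape[1])
            cols.append(d)
            pos += d.shape[1]

        for term in self.smooth_terms:
            basis = MarginalBasis.from_data(X[term.cov].to_numpy(), term.k)
            b = basis.design(X[term.cov].to_numpy())
            means = b.mean(axis=0)
            b = b - means
            sl = slice(pos, pos + term.k)
            penalties.append((sl, difference_penalty(term.k, term.order)))
            meta["terms"].append(
                {"kind": "smooth", "term": term, "bases": [basis],
                 "means": means, "slice": sl}
            )
            cols.append(b)
            pos += term.k

        for term in self.tensor_terms:
            bases = [
                MarginalBasis.from_data(X[c].to_numpy(), term.k)
                for c in term.covs
            ]
            t_mat = tensor_design(
                [bs.design(X[c].to_numpy()) for bs, c in zip(bases, term.covs)]
            )
            means = t_mat.mean(axis=0)
            t_mat = t_mat - means
            pens = tensor_penalties([term.k] * len(term.covs), term.order)
            if term.by is None:
                width = t_mat.shape[1]
                sl = slice(pos, pos + width)
                block = t_mat
                for p in pens:
                    penalties.append((sl, p))
                by_levels = None
            else:
                by_levels = sorted(pd.unique(X[term.by]))
                blocks = [
                    t_mat * (X[term.by].to_numpy() == lv)[:, None]
                    for lv in by_levels
                ]
                block = np.hstack(blocks)
                width = block.shape[1]
                sl = slice(pos, pos + width)
                from scipy.linalg import block_diag

                for p in pens:  # shared smoothing across levels per margin
                    penalties.append(
                        (sl, block_diag(*([p] * len(by_levels))))
                    )
            meta["terms"].append(
                {"kind": "tensor", "term": term, "bases": bases,
                 "means": means, "slice": sl, "by_levels": by_levels}
            )
            cols.append(block)
            pos += width

        if self.random_intercept is not None:
            levels = sorted(pd.unique(X[self.random_intercept]))
            meta["ri_levels"] = levels
            d = _factor_dummies(
                X[self.random_intercept], levels, drop_first=False
            )
            sl = slice(pos, pos + len(levels))
            penalties.append((sl, np.eye(len(levels))))
            meta["ri_slice"] = sl
            cols.append(d)
            pos += len(levels)

        return np.hstack(cols), penalties, meta

    def _build_prediction_design(
        self, X: pd.DataFrame, include_random: bool
    ) -> np.ndarray:
        meta = self._meta_
        n = len(X)
        cols = [np.ones((n, 1))]
        if self.factor is not None:
            levels = meta["factor_levels"]
            unseen = set(pd.unique(X[self.factor])) - set(levels)
            if unseen:
                raise ValueError(f"unseen {self.factor} levels: {sorted(unseen)}")
            cols.append(_factor_dummies(X[self.factor], levels))
        for info in meta["terms"]:
            term = info["term"]
            if info["kind"] == "smooth":
                b = info["bases"][0].design(X[term.cov].to_numpy())
                cols.append(b - info["means"])
            else:
                t_mat = tensor_design(
                    [
                        bs.design(X[c].to_numpy())
                        for bs, c in zip(info["bases"], term.covs)
                    ]
                ) - info["means"]
                if info["by_levels"] is None:
                    cols.append(t_mat)
                else:
                    for lv in info["by_levels"]:
                        cols.append(
                            t_mat * (X[term.by].to_numpy() == lv)[:, None]
                        )
        if self.random_intercept is not None:
            levels = meta["ri_levels"]
            if include_random:
                d = np.zeros((n, len(levels)))
                idx = {lv: j for j, lv in enumerate(levels)}
                for i, lv in enumerate(X[self.random_intercept]):
                    j = idx.get(lv)
                    if j is not None:
                        d[i, j] = 1.0
                cols.append(d)
            else:
                cols.append(np.zeros((n, len(levels))))
        return np.hstack(cols)

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y, fix_smoothing=None):
        """Fit by penalized (IRLS) least squares with GCV-chosen smoothing.

        ``fix_smoothing`` freezes the log smoothing parameters (one per
        penalty) instead of optimizing them — used for large-penalty limits
        and for fast refits in cross-validation.
        """
        self._validate_terms()
        if self.criterion != "gcv":
            raise NotImplementedError("only GCV smoothing selection is implemented")
        y = np.asarray(y, dtype=float)
        if self.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial family requires a 0/1 response")
        xmat, penalties, meta = self._build_training_design(X)
        n, p = xmat.shape
        n_pen = len(penalties)

        def solve(rho, beta0=None):
            return self._penalized_fit(xmat, y, penalties, rho, beta0)

        if n_pen == 0:
            rho = np.array([])
            state = solve(rho)
        elif fix_smoothing is not None:
            rho = np.asarray(fix_smoothing, dtype=float)
            if rho.size != n_pen:
                raise ValueError(
                    f"fix_smoothing needs {n_pen} values, got {rho.size}"
                )
            state = solve(rho)
        else:
            warm = {"beta": None}

            def objective(rho):
                try:
                    st = solve(rho, warm["beta"])
                except np.linalg.LinAlgError:
                    return 1e12
                warm["beta"] = st["beta"]
                return st["gcv"]

            res = optimize.minimize(
                objective,
                np.zeros(n_pen),
                method="Nelder-Mead",
                options={
                    "maxfev": self.optimizer_maxfev,
                    "xatol": 0.05,
                    "fatol": 1e-7,
                },
            )
            rho = res.x
            state = solve(rho, warm["beta"])

        self._meta_ = meta
        self._penalties_ = penalties
        self.n_obs_ = n
        self.coef_ = state["beta"]
        self.edf_ = state["edf"]
        self.gcv_ = state["gcv"]
        self.criterion_ = self.criterion
        self.smoothing_params_ = np.exp(rho)
        self.log_smoothing_ = rho
        self.fitted_link_ = xmat @ state["beta"]
        if self.family == "gaussian":
            self.fitted_response_ = self.fitted_link_
            rss = float(np.sum((y - self.fitted_link_) ** 2))
            self.scale_ = rss / max(n - self.edf_, 1.0)
            tss = float(np.sum((y - y.mean()) ** 2))
            self.deviance_ = rss
            self.null_deviance_ = tss
            self.aic_ = (
                n * np.log(2 * np.pi * rss / n) + n + 2 * (self.edf_ + 1)
            )
        else:
            self.fitted_response_ = _sigmoid(self.fitted_link_)
            dev = _binomial_deviance(y, self.fitted_response_)
            mu0 = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
            self.scale_ = 1.0
            self.deviance_ = dev
            self.null_deviance_ = _binomial_deviance(y, np.full(n, mu0))
            self.aic_ = dev + 2 * self.edf_
        self.deviance_explained_ = (
            max(0.0, 1.0 - self.deviance_ / self.null_deviance_)
            if self.null_deviance_ > 0
            else 0.0
        )
        self.residuals_ = y - self.fitted_response_
        self._chol_ = state["chol"]
        if self.random_intercept is not None:
            lam_ri = float(np.exp(rho[-1])) if rho.size else 1.0
            self.random_intercept_var_ = self.scale_ / lam_ri
        else:
            self.random_intercept_var_ = 0.0
        self._y_hash_ = hashlib.sha256(
            np.ascontiguousarray(y).tobytes()
        ).hexdigest()
        self._y_ = y
        return self

    def _penalized_fit(self, xmat, y, penalties, rho, beta0=None):
        n, p = xmat.shape
        s_total = np.zeros((p, p))
        for (sl, mat), r in zip(penalties, rho):
            s_total[sl, sl] += np.exp(r) * mat
        s_total[np.diag_indices(p)] += 1e-9  # numerical safeguard
        s_total[0, 0] -= 1e-9  # keep the intercept unpenalized

        if self.family == "gaussian":
            xtx = xmat.T @ xmat
            c, low = _robust_cho_factor(xtx + s_total)
            beta = cho_solve((c, low), xmat.T @ y)
            edf = float(np.trace(cho_solve((c, low), xtx)))
            rss = float(np.sum((y - xmat @ beta) ** 2))
            denom = max(n - edf, 1e-6)
            gcv = n * rss / denom**2
            return {"beta": beta, "edf": edf, "gcv": gcv, "chol": (c, low)}

        # binomial PIRLS
        if beta0 is None:
            beta = np.zeros(p)
            beta[0] = _logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        else:
            beta = beta0.copy()
        dev_prev = np.inf
        c = low = None
        xtwx = None
        for _ in range(self.max_pirls):
            eta = xmat @ beta
            mu = _sigmoid(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            xw = xmat * w[:, None]
            xtwx = xmat.T @ xw
            c, low = _robust_cho_factor(xtwx + s_total)
            beta = cho_solve((c, low), xw.T @ z)
            dev = _binomial_deviance(y, _sigmoid(xmat @ beta))
            if abs(dev_prev - dev) < self.tol * (abs(dev) + 0.1):
                dev_prev = dev
                break
            dev_prev = dev
        else:
            warnings.warn(
                f"PIRLS did not converge; last deviance {dev_prev:.6g}"
            )
        edf = float(np.trace(cho_solve((c, low), xtwx)))
        denom = max(n - edf, 1e-6)
        gcv = n * dev_prev / denom**2
        return {"beta": beta, "edf": edf, "gcv": gcv, "chol": (c, low)}

    # -- prediction ---------------------------------------------------------

    def predict(
        self, X: pd.DataFrame, type: str = "response",
        include_random: bool = False,
    ) -> np.ndarray:
        """Predict on the link or response scale.

        Covariates outside the training range are clamped (consistent with
        upstream truncation).  Random intercepts are excluded by default
        (population-level prediction at new locations).
        """
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted")
        xmat = self._build_prediction_design(X, include_random)
        eta = xmat @ self.coef_
        if type == "link" or self.family == "gaussian":
            return eta
        if type == "response":
            return _sigmoid(eta)
        raise ValueError(f"unknown prediction type {type!r}")

    def coef_covariance(self) -> np.ndarray:
        """Bayesian posterior covariance of the coefficients, phi*(X'WX+S)^-1."""
        p = self.coef_.size
        return self.scale_ * cho_solve(self._chol_, np.eye(p))


def _robust_cho_factor(a: np.ndarray):
    """Cholesky with a progressively scaled diagonal boost; extreme
    smoothing parameters can push the system past double precision."""
    scale = float(np.mean(np.diag(a))) + 1.0
    for eps in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return cho_factor(a + eps * scale * np.eye(a.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("penalized system is not positive definite")


def _factor_dummies(values, levels, drop_first: bool = True) -> np.ndarray:
    arr = np.asarray(values)
    use = levels[1:] if drop_first else levels
    return np.column_stack([(arr == lv).astype(float) for lv in use])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _logit(p):
    return np.log(p / (1 - p))


def _binomial_deviance(y, mu):
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(mu) + (1 - y) * np.log(1 - mu)
    return float(-2.0 * np.sum(ll))


# --------------------------------------------------------------------------
# cross-validation and period contrasts
# --------------------------------------------------------------------------

def cross_validate(
    model: PenalizedGAM,
    X: pd.DataFrame,
    y,
    groups=None,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Station-grouped k-fold cross-validation of a fitted model.

    Folds are formed over stations (or the supplied ``groups``) so that
    replicates of one station never straddle the train/test split.  Held-out
    refits reuse the full-model smoothing parameters.  Returns the
    in-sample scale error ``gs`` (mean squared residual on the model
    scale), the cross-validation error ``xv`` and ``d_pct = 100*(xv-gs)/gs``
    computed from unrounded values, plus the recorded fold assignment.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(y, dtype=float)
    if groups is None:
        groups = (
            X[model.random_intercept].to_numpy()
            if model.random_intercept
            else np.arange(len(X))
        )
    groups = np.asarray(groups)
    if not hasattr(model, "coef_"):
        model.fit(X, y)
    rho = model.log_smoothing_

    uniq = np.unique(groups)
    for attempt in range(10):
        rng = np.random.default_rng([seed, attempt, 17])
        perm = rng.permutation(uniq)
        fold_of_group = {g: i % folds for i, g in enumerate(perm)}
        assign = np.array([fold_of_group[g] for g in groups])
        if model.family != "binomial":
            break
        ok = all(y[assign != f].sum() > 0 for f in range(folds))
        if ok:
            break
        warnings.warn(f"fold with no positive rows; resampling (attempt {attempt})")
    preds = np.empty(len(y))
    for f in range(folds):
        tr = assign != f
        m = PenalizedGAM(**model.get_params())
        m.fit(X[tr], y[tr], fix_smoothing=rho)
        preds[~tr] = m.predict(X[~tr], type="response")
    # population-level in-sample error (random intercepts excluded), the
    # quantity comparable to CV predictions at unseen stations
    gs = float(np.mean((y - model.predict(X, type="response")) ** 2))
    xv = float(np.mean((y - preds) ** 2))
    d_pct = 100.0 * (xv - gs) / gs if gs > 0 else np.nan
    return {"gs": gs, "xv": xv, "d_pct": d_pct, "fold_assignment": assign,
            "seed": seed}


def compare_periods(fit: PenalizedGAM, alpha: float = 0.05) -> dict:
    """All pairwise period contrasts with Holm-adjusted p-values.

    Returns the contrast table and an ordering summary such as
    ``"P3 < P1 < P2"`` (levels separated by ``", "`` when the adjacent
    contrast is not significant).
    """
    from statsmodels.stats.multitest import multipletests

    if fit.factor is None:
        raise ValueError("fit has no period fixed factor")
    levels = fit._meta_["factor_levels"]
    if len(levels) < 2:
        raise ValueError("need at least 2 period levels")
    sl = fit._meta_["factor_slice"]
    vb = fit.coef_covariance()
    # treatment coding: effect of baseline level is 0
    eff = np.r_[0.0, fit.coef_[sl]]
    idx = np.r_[0, np.arange(sl.start, sl.stop)]  # 0 = intercept placeholder

    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            diff = eff[i] - eff[j]
            var = 0.0
            if i > 0:
                var += vb[idx[i], idx[i]]
            if j > 0:
                var += vb[idx[j], idx[j]]
            if i > 0 and j > 0:
                var -= 2 * vb[idx[i], idx[j]]
            se = np.sqrt(max(var, 1e-300))
            z = diff / se if se > 0 else 0.0
            pval = 2 * norm.sf(abs(z)) if se > 0 else 1.0
            rows.append(
                {"contrast": f"{levels[i]}-{levels[j]}", "estimate": diff,
                 "se": se, "z": z, "p": pval}
            )
    table = pd.DataFrame(rows)
    reject, p_adj, *_ = multipletests(table["p"], alpha=alpha, method="holm")
    table["p_holm"] = p_adj
    table["significant"] = reject

    order = np.argsort(eff)
    sig = {
        frozenset(r["contrast"].split("-")): r["significant"]
        for r in table.to_dict("records")
    }
    parts = [levels[order[0]]]
    for a, b in zip(order[:-1], order[1:]):
        sep = " < " if sig[frozenset((levels[a], levels[b]))] else ", "
        parts.append(sep + levels[b])
    return {"contrasts": table, "ordering": "".join(parts)}
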