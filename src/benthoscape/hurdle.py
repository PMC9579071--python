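"""Zero-inflation handling: model-form decision rule and hurdle models.

Benthic biomass records are frequently zero-inflated.  The model form for
each prey group is chosen from its fraction of exact-zero biomass values:

* ≤ 10% zeros — a single unconditional Gaussian model on ln(X+0.5);
* between 10% and 50% — a hurdle model: a logistic occupancy model on all
  rows plus a conditional Gaussian model on the positive rows only, with
  the unconditional prediction formed as the product of the predicted
  occupancy probability and the back-transformed conditional prediction;
* ≥ 50% — a logistic occupancy model only (too few positive values to
  model the conditional part); such groups are reported as probability
  surfaces and never converted to energy units.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .gam import PenalizedGAM, inverse_transform, transform_response

__all__ = [
    "ModelForm",
    "DecisionThresholds",
    "choose_model_form",
    "HurdleGAM",
    "fit_hurdle",
    "unconditional_prediction",
]


class ModelForm(str, Enum):
    UNCONDITIONAL = "UNCONDITIONAL"
    HURDLE = "HURDLE"
    LOGISTIC_ONLY = "LOGISTIC_ONLY"


@dataclass(frozen=True)
class DecisionThresholds:
    """Zero-fraction cut points for the model-form decision."""

    unconditional_max: float = 0.10
    logistic_min: float = 0.50

    def __post_init__(self):
        if not 0 < self.unconditional_max < self.logistic_min < 1:
            raise ValueError(
                "require 0 < unconditional_max < logistic_min < 1"
            )


def choose_model_form(
    zero_fraction: float, d: DecisionThresholds = DecisionThresholds()
) -> ModelForm:
    """Decide the model form from the proportion of exact zeros.

    Exactly 10% zeros still takes the unconditional form ("10% or less");
    exactly 50% already takes the logistic-only form (the hurdle requires
    strictly less than 50%).
    """
    z = float(zero_fraction)
    if not 0.0 <= z <= 1.0:
        raise ValueError("zero_fraction must be in [0, 1]")
    if z <= d.unconditional_max:
        return ModelForm.UNCONDITIONAL
    if z < d.logistic_min:
        return ModelForm.HURDLE
    return ModelForm.LOGISTIC_ONLY


class HurdleGAM(BaseEstimator):
    """Two-part hurdle model: logistic occupancy x conditional Gaussian.

    The occupancy part is a binomial :class:`PenalizedGAM` fitted to
    indicator(biomass > 0) over all rows; the conditional part is a
    Gaussian :class:`PenalizedGAM` fitted to ln(X+0.5)-transformed values
    over strictly the positive rows.  ``predict`` composes the two parts
    as p_hat x max(exp(conditional) - 0.5, 0).

    Constructor parameters mirror :class:`PenalizedGAM`; the same model
    structure is used for both parts unless ``conditional_params``
    overrides entries for the conditional part.
    """

    def __init__(
        self,
        smooth_terms=(),
        tensor_terms=(),
        factor: str | None = None,
        random_intercept: str | None = None,
        transform_offset: float = 0.5,
        conditional_params: dict | None = None,
        optimizer_maxfev: int = 150,
    ):
        self.smooth_terms = tuple(smooth_terms)
        self.tensor_terms = tuple(tensor_terms)
        self.factor = factor
        self.random_intercept = random_intercept
        self.transform_offset = transform_offset
        self.conditional_params = conditional_params
        self.optimizer_maxfev = optimizer_maxfev

    def _part_params(self) -> dict:
        return {
            "smooth_terms": self.smooth_terms,
            "tensor_terms": self.tensor_terms,
            "factor": self.factor,
            "random_intercept": self.random_intercept,
            "optimizer_maxfev": self.optimizer_maxfev,
        }

    def fit(self, X: pd.DataFrame, biomass):
        """Fit both parts; requires both zero and positive biomass rows."""
        b = np.asarray(biomass, dtype=float)
        present = b > 0
        if present.all():
            raise ValueError(
                "no zero rows: use the UNCONDITIONAL model form instead"
            )
        if not present.any():
            raise ValueError(
                "no positive rows: use the LOGISTIC_ONLY model form instead"
            )
        self.occupancy_ = PenalizedGAM(
            family="binomial", **self._part_params()
        ).fit(X, present.astype(float))
        cond_params = self._part_params()
        if self.conditional_params:
            cond_params.update(self.conditional_params)
        y_cond = transform_response(b[present], self.transform_offset)
        self.conditional_ = PenalizedGAM(
            family="gaussian", **cond_params
        ).fit(X[present], y_cond)
        self.n_positive_ = int(present.sum())
        self.zero_fraction_ = 1.0 - self.n_positive_ / len(b)
        return self

    def predict(self, X: pd.DataFrame, parts: bool = False):
        """Unconditional response-scale prediction p_hat x conditional.

        With ``parts=True`` returns ``(unconditional, p_hat, conditional)``.
        """
        p_hat = self.occupancy_.predict(X, type="response")
        cond = inverse_transform(
            self.conditional_.predict(X), self.transform_offset, clip=True
        )
        unconditional = p_hat * cond
        if parts:
            return unconditional, p_hat, cond
        return unconditional


def fit_hurdle(X: pd.DataFrame, biomass, **params) -> HurdleGAM:
    """Thin functional wrapper over :class:`HurdleGAM`."""
    return HurdleGAM(**params).fit(X, biomass)


def unconditional_prediction(h: HurdleGAM, newdata: pd.DataFrame) -> np.ndarray:
    """Response-scale unconditional prediction of a fitted hurdle model."""
    return h.predict(newdata)
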