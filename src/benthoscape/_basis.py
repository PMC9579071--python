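"""Penalized B-spline bases and difference penalties (P-splines).

Cubic B-spline bases on equally spaced knots with discrete difference
penalties; tensor-product bases are row-wise Kronecker products of the
marginal bases with one penalty per margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["MarginalBasis", "difference_penalty", "tensor_design", "tensor_penalties"]


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """k x k penalty matrix D'D from order-th discrete differences."""
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


@dataclass
class MarginalBasis:
    """Cubic B-spline basis on equally spaced knots over the data range."""

    k: int
    xmin: float
    xmax: float
    degree: int = 3

    @classmethod
    def from_data(cls, x: np.ndarray, k: int) -> "MarginalBasis":
        x = np.asarray(x, dtype=float)
        if np.unique(x).size < k:
            raise ValueError(
                f"need at least k={k} unique covariate values, "
                f"got {np.unique(x).size}"
            )
        xmin, xmax = float(np.min(x)), float(np.max(x))
        if xmax <= xmin:
            raise ValueError("degenerate covariate range")
        return cls(k=k, xmin=xmin, xmax=xmax)

    @property
    def knots(self) -> np.ndarray:
        # equally spaced knots extended beyond the data range (standard
        # P-spline construction), so the difference-penalty nullspace is
        # exactly the polynomials of degree < penalty order
        d = self.degree
        if self.k <= d:
            raise ValueError(f"k={self.k} too small for degree {d}")
        h = (self.xmax - self.xmin) / (self.k - d)
        return self.xmin + h * (np.arange(self.k + d + 1) - d)

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis; out-of-range values are clamped to the
        training range (covariates are truncated upstream anyway)."""
        t = self.knots
        d = self.degree
        # clamp to the exact representable support [t[d], t[-d-1]]
        x = np.clip(np.asarray(x, dtype=float), t[d], t[-d - 1])
        return BSpline.design_matrix(x, t, d, extrapolate=False).toarray()


def tensor_design(margins: list[np.ndarray]) -> np.ndarray:
    """Row-wise Kronecker product of 2 or 3 marginal design matrices."""
    out = margins[0]
    for b in margins[1:]:
        n, k1 = out.shape
        k2 = b.shape[1]
        out = (out[:, :, None] * b[:, None, :]).reshape(n, k1 * k2)
    return out


def tensor_penalties(ks: list[int], order: int = 2) -> list[np.ndarray]:
    """One penalty per margin: kron of the margin's difference penalty with
    identities on the other margins."""
    pens = []
    for m, km in enumerate(ks):
        mats = [
            difference_penalty(km, order) if j == m else np.eye(kj)
            for j, kj in enumerate(ks)
        ]
        s = mats[0]
        for mat in mats[1:]:
            s = np.kron(s, mat)
        pens.append(s)
    return pens
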