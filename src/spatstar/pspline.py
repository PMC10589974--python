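"""Penalised B-spline (P-spline) bases for smooth covariate effects.

A P-spline represents a smooth function f(x) as a B-spline expansion
``f(x) = B(x) @ gamma`` with a difference penalty ``gamma' P gamma``,
``P = D_d' D_d`` for the d-th order difference operator ``D_d``. In the
Bayesian reading the penalty is a d-th order random-walk prior on the
coefficients with variance ``tau2_spline``.

Construction used here (documented because conventions vary): ``n_knots``
equally spaced knots span ``[min(x), max(x)]`` *including both boundaries*;
the boundary knots are then repeated ``degree`` extra times (clamped basis),
giving ``n_knots + degree - 1`` basis functions, i.e.
``(interior knots) + degree + 1`` with ``interior = n_knots - 2``. The
clamped basis satisfies partition of unity on the whole span, which the
sampler exploits to absorb the smooth's level into the intercept exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_pspline_basis"]


@dataclass
class SplineBasis:
    """Evaluated B-spline basis with its difference penalty.

    Attributes
    ----------
    knots : full (clamped) knot vector
    degree, penalty_order : ints
    basis : (n, B) evaluation at the construction points
    penalty : (B, B) positive-semidefinite difference penalty, nullity equal
        to ``penalty_order``
    """

    knots: np.ndarray
    degree: int
    penalty_order: int
    basis: np.ndarray
    penalty: np.ndarray
    x_min: float
    x_max: float

    @property
    def n_basis(self) -> int:
        return self.basis.shape[1]

    @property
    def penalty_rank(self) -> int:
        return self.n_basis - self.penalty_order

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at new points (clipped to the knot span)."""
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        out = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return out


def build_pspline_basis(x, n_knots: int = 22, degree: int = 3, penalty_order: int = 2) -> SplineBasis:
    """Build a clamped, equally spaced B-spline basis with difference penalty.

    Parameters
    ----------
    x : 1-d array of covariate values (at least ``degree + 1`` distinct).
    n_knots : number of equally spaced knots spanning ``[min(x), max(x)]``
        including both boundaries (so ``n_knots - 2`` interior knots). The
        default, with cubic degree, reproduces a 20-interior-knot cubic basis.
    degree : B-spline degree (>= 1).
    penalty_order : order of the difference penalty / random walk (>= 1,
        must satisfy ``n_knots >= penalty_order + 1``).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty covariate vector")
    distinct = np.unique(x)
    if distinct.size < degree + 1:
        raise ValueError(
            f"need at least degree+1={degree + 1} distinct covariate values, got {distinct.size}"
        )
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if penalty_order < 1 or n_knots < penalty_order + 1:
        raise ValueError("need n_knots >= penalty_order + 1 and penalty_order >= 1")
    lo, hi = float(distinct[0]), float(distinct[-1])
    inner = np.linspace(lo, hi, int(n_knots))
    knots = np.concatenate([np.full(degree, lo), inner, np.full(degree, hi)])
    basis = BSpline.design_matrix(x, knots, degree).toarray()
    nb = basis.shape[1]
    d = np.diff(np.eye(nb), n=penalty_order, axis=0)
    penalty = d.T @ d
    return SplineBasis(knots, int(degree), int(penalty_order), basis, penalty, lo, hi)
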