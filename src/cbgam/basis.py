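"""B-spline basis construction for the additive-model smooths.

A smooth term is represented by ``n_splines`` B-spline basis functions of a
given degree over a knot vector whose boundary knots cover the training
range and whose interior knots sit at equally spaced quantiles of the
training data.  Knot vectors are computed once from the full cohort and can
be frozen, so bootstrap refits share the same basis and their coefficients
are directly averageable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "build_basis", "second_difference_matrix"]


@dataclass
class SplineSpec:
    """Basis description of one smooth: size, degree, and full knot vector."""

    n_splines: int
    degree: int = 3
    knots: np.ndarray = field(default=None)  # len = n_splines + degree + 1

    def __post_init__(self):
        if self.n_splines < self.degree + 1:
            raise ValueError("n_splines must be >= degree + 1")
        if self.knots is not None:
            self.knots = np.asarray(self.knots, dtype=float)
            if len(self.knots) != self.n_splines + self.degree + 1:
                raise ValueError(
                    f"knot vector length {len(self.knots)} != "
                    f"n_splines + degree + 1 = {self.n_splines + self.degree + 1}"
                )
            if (np.diff(self.knots) < 0).any():
                raise ValueError("knots must be non-decreasing")

    @property
    def boundary(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    @classmethod
    def from_data(cls, x, n_splines: int, degree: int = 3) -> "SplineSpec":
        """Quantile-based knots: boundary at data min/max (repeated degree+1
        times), interior at equally spaced quantiles."""
        x = np.asarray(x, dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if not hi > lo:
            raise ValueError("cannot place knots on a constant variable")
        n_interior = n_splines - degree - 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
            # heavy-tailed data can collapse quantiles; fall back to an even grid
            if (np.diff(np.concatenate([[lo], interior, [hi]])) <= 0).any():
                interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        else:
            interior = np.array([])
        knots = np.concatenate(
            [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
        )
        return cls(n_splines=n_splines, degree=degree, knots=knots)


def build_basis(x, spec: SplineSpec, clamp: bool = True) -> np.ndarray:
    """Evaluate the B-spline design matrix, shape (len(x), n_splines).

    Out-of-range points are clamped to the boundary knots when ``clamp`` is
    true (constant extrapolation of the basis), otherwise an error is raised.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = spec.boundary
    if clamp:
        x = np.clip(x, lo, hi)
    elif ((x < lo) | (x > hi)).any():
        raise ValueError(f"x outside boundary knots [{lo}, {hi}]")
    B = BSpline.design_matrix(x, spec.knots, spec.degree, extrapolate=False)
    return np.asarray(B.todense())


def greville_sites(spec: SplineSpec) -> np.ndarray:
    """Greville abscissae: knot averages at which each basis function acts.
    A coefficient vector affine in these sites represents an exactly linear
    function (B-spline linear precision)."""
    k, t = spec.degree, spec.knots
    return np.array([t[j + 1 : j + k + 1].mean() for j in range(spec.n_splines)])


def second_difference_matrix(m: int, sites=None) -> np.ndarray:
    """Second-order difference operator D2 (shape (m-2, m)): the P-spline
    penalty is ||D2 @ beta||^2.

    With ``sites`` (the Greville abscissae, possibly unevenly spaced) the
    rows are scaled divided differences, so the penalty null space is the
    set of coefficient vectors affine in the sites — i.e. exactly the
    linear functions of x, whatever the knot spacing.  For evenly spaced
    sites this reduces to the classic (1, -2, 1) stencil.
    """
    if m < 3:
        return np.zeros((0, m))
    D = np.zeros((m - 2, m))
    if sites is None:
        for i in range(m - 2):
            D[i, i : i + 3] = (1.0, -2.0, 1.0)
        return D
    sites = np.asarray(sites, dtype=float)
    if len(sites) != m:
        raise ValueError("sites length must equal basis size")
    for i in range(m - 2):
        d1 = sites[i + 1] - sites[i]
        d2 = sites[i + 2] - sites[i + 1]
        # rows scaled by the smaller adjacent gap: bounded entries even for
        # wildly uneven quantile spacing, so smoothing stays adaptive on the
        # quantile scale while the null space stays exactly linear
        c = min(d1, d2)
        D[i, i : i + 3] = (c / d1, -(c / d1 + c / d2), c / d2)
    return D
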