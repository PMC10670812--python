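"""Penalized logistic additive model (P-spline GAM) fitted by PIRLS.

The model for a binary endpoint y (here: clinical benefit) is

    logit P(y = 1 | x) = beta0 + sum_j f_j(x_j) + sum_k g_k(c_k)

where each continuous smooth f_j is a linear combination of B-spline basis
functions with a second-order difference (P-spline) penalty on its
coefficients, and each categorical term g_k carries one coefficient per
state under a frequency-weighted sum-to-zero constraint (so every state has
a defined estimate, not just non-reference contrasts).  Smooths are centered
over the training covariate values; the intercept absorbs the means.

Fitting maximizes the Bernoulli log-likelihood minus
(lambda/2) * sum_j ||D2 beta_j||^2 by penalized iteratively reweighted least
squares with step-halving.  A tiny ridge on all non-intercept coefficients
makes the penalized Hessian strictly positive definite (the difference
penalty has a null space); on complete separation the fit is automatically
re-stabilized with a larger ridge and a warning.

In the high-lambda limit each smooth collapses to a straight line (the
penalty null space), recovering an ordinary linear-logit fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin

from .basis import SplineSpec, build_basis, greville_sites, second_difference_matrix

__all__ = ["PSplineLogisticGAM", "PartialEffectCurve", "TermLayout", "build_layout"]

_PROB_CLIP = 1e-10
_COEF_BLOWUP = 30.0


class ConvergenceError(RuntimeError):
    """PIRLS failed to converge; carries the penalized-deviance trace."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class PartialEffectCurve:
    """Centered smooth effect of one variable on the log-odds scale."""

    variable: str
    x: np.ndarray                     # grid in model (fit-scale) units
    values: np.ndarray                # centered f(x), log-odds
    x_raw: np.ndarray | None = None   # grid mapped back to raw units
    spread: np.ndarray | None = None  # pointwise bootstrap sd, if ensembled

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if (np.diff(self.x) <= 0).any():
            raise ValueError("grid must be strictly increasing")
        if self.x_raw is not None:
            self.x_raw = np.asarray(self.x_raw, dtype=float)
            if (np.diff(self.x_raw) <= 0).any():
                raise ValueError("raw grid must be strictly increasing")


@dataclass
class TermLayout:
    """Frozen design description shared across bootstrap refits.

    Holds, per continuous term, the spline spec and training-mean basis
    centers; per categorical term, the state list, frequency weights and
    the sum-to-zero contrast basis Z (k states -> k-1 free parameters).
    """

    numeric_terms: list
    categorical_terms: list
    specs: dict = field(default_factory=dict)      # var -> SplineSpec
    centers: dict = field(default_factory=dict)    # var -> basis column means
    levels: dict = field(default_factory=dict)     # var -> list of states
    weights: dict = field(default_factory=dict)    # var -> freq weights (sum 1)
    contrasts: dict = field(default_factory=dict)  # var -> Z (k x (k-1))
    slices: dict = field(default_factory=dict)     # var -> slice into coef
    n_coef: int = 0

    def to_dict(self) -> dict:
        return {
            "numeric_terms": list(self.numeric_terms),
            "categorical_terms": list(self.categorical_terms),
            "specs": {
                v: {"n_splines": s.n_splines, "degree": s.degree,
                    "knots": s.knots.tolist()}
                for v, s in self.specs.items()
            },
            "centers": {v: c.tolist() for v, c in self.centers.items()},
            "levels": {v: list(l) for v, l in self.levels.items()},
            "weights": {v: w.tolist() for v, w in self.weights.items()},
            "contrasts": {v: z.tolist() for v, z in self.contrasts.items()},
            "slices": {v: [s.start, s.stop] for v, s in self.slices.items()},
            "n_coef": self.n_coef,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TermLayout":
        lay = cls(
            numeric_terms=list(d["numeric_terms"]),
            categorical_terms=list(d["categorical_terms"]),
        )
        lay.specs = {
            v: SplineSpec(s["n_splines"], s["degree"], np.array(s["knots"]))
            for v, s in d["specs"].items()
        }
        lay.centers = {v: np.array(c) for v, c in d["centers"].items()}
        lay.levels = {v: list(l) for v, l in d["levels"].items()}
        lay.weights = {v: np.array(w) for v, w in d["weights"].items()}
        lay.contrasts = {v: np.array(z) for v, z in d["contrasts"].items()}
        lay.slices = {v: slice(s[0], s[1]) for v, s in d["slices"].items()}
        lay.n_coef = int(d["n_coef"])
        return lay


def build_layout(
    X: pd.DataFrame,
    numeric_terms,
    categorical_terms,
    n_splines: int,
    degree: int = 3,
) -> TermLayout:
    """Compute a frozen layout (knots, centers, codings) from reference data."""
    lay = TermLayout(list(numeric_terms), list(categorical_terms))
    pos = 1  # 0 is the intercept
    for var in lay.numeric_terms:
        spec = SplineSpec.from_data(X[var].to_numpy(dtype=float), n_splines, degree)
        B = build_basis(X[var].to_numpy(dtype=float), spec)
        lay.specs[var] = spec
        lay.centers[var] = B.mean(axis=0)
        lay.slices[var] = slice(pos, pos + n_splines)
        pos += n_splines
    for var in lay.categorical_terms:
        levels = sorted(pd.unique(X[var]).tolist())
        counts = X[var].value_counts()
        w = np.array([counts.get(lv, 0) for lv in levels], dtype=float)
        w = w / w.sum()
        Z = linalg.null_space(w.reshape(1, -1))  # k x (k-1), orthonormal
        lay.levels[var] = levels
        lay.weights[var] = w
        lay.contrasts[var] = Z
        k = len(levels) - 1
        lay.slices[var] = slice(pos, pos + k)
        pos += k
    lay.n_coef = pos
    return lay


def _design(X: pd.DataFrame, lay: TermLayout, clamp: bool = True) -> np.ndarray:
    n = len(X)
    M = np.zeros((n, lay.n_coef))
    M[:, 0] = 1.0
    for var in lay.numeric_terms:
        B = build_basis(X[var].to_numpy(dtype=float), lay.specs[var], clamp=clamp)
        M[:, lay.slices[var]] = B - lay.centers[var]
    for var in lay.categorical_terms:
        cat = pd.Categorical(X[var], categories=lay.levels[var])
        if (cat.codes < 0).any():
            bad = sorted(set(np.asarray(X[var])[cat.codes < 0]))
            raise ValueError(f"unseen state(s) {bad} for categorical term {var!r}")
        eye = np.eye(len(lay.levels[var]))
        M[:, lay.slices[var]] = (eye @ lay.contrasts[var])[cat.codes]
    return M


def _penalty(lay: TermLayout, lam: float, ridge: float) -> np.ndarray:
    P = np.zeros((lay.n_coef, lay.n_coef))
    for var in lay.numeric_terms:
        s = lay.slices[var]
        D = second_difference_matrix(
            s.stop - s.start, sites=greville_sites(lay.specs[var])
        )
        P[s, s] = lam * (D.T @ D)
    idx = np.arange(1, lay.n_coef)
    P[idx, idx] += ridge
    return P


def _bernoulli_deviance(y, mu):
    mu = np.clip(mu, _PROB_CLIP, 1 - _PROB_CLIP)
    return -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))


class PSplineLogisticGAM(BaseEstimator, ClassifierMixin):
    """Penalized logistic GAM with B-spline smooths and sum-to-zero factors.

    Parameters
    ----------
    numeric_terms, categorical_terms : lists of column names; inferred from
        dtypes when None (numeric dtype -> smooth, anything else -> factor).
    n_splines : basis size per smooth.
    degree : B-spline degree (cubic by default).
    lam : second-difference penalty strength (>= 0).
    ridge : small ridge on non-intercept coefficients for identifiability.
    separation_ridge : ridge used for the automatic stabilized refit when
        complete separation is detected.
    layout : a frozen :class:`TermLayout`; when given, knots, basis centers
        and categorical codings are taken from it instead of the fit data
        (required for coefficient averaging across bootstrap refits).
    clamp : clamp out-of-range covariates to the knot boundary at predict
        time (raise when False).
    """

    def __init__(
        self,
        numeric_terms=None,
        categorical_terms=None,
        n_splines: int = 8,
        degree: int = 3,
        lam: float = 1.0,
        ridge: float = 1e-8,
        separation_ridge: float = 0.1,
        max_iter: int = 100,
        tol: float = 1e-8,
        layout: TermLayout | None = None,
        clamp: bool = True,
    ):
        self.numeric_terms = numeric_terms
        self.categorical_terms = categorical_terms
        self.n_splines = n_splines
        self.degree = degree
        self.lam = lam
        self.ridge = ridge
        self.separation_ridge = separation_ridge
        self.max_iter = max_iter
        self.tol = tol
        self.layout = layout
        self.clamp = clamp

    # -- fitting ----------------------------------------------------------
    def _resolve_terms(self, X: pd.DataFrame):
        if self.numeric_terms is not None or self.categorical_terms is not None:
            return list(self.numeric_terms or []), list(self.categorical_terms or [])
        num = [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])]
        cat = [c for c in X.columns if c not in num]
        return num, cat

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of model terms")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("y must contain exactly two classes")
        yb = (y == self.classes_[1]).astype(float)
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

        if self.layout is not None:
            lay = self.layout
        else:
            num, cat = self._resolve_terms(X)
            lay = build_layout(X, num, cat, self.n_splines, self.degree)
        self.layout_ = lay

        M = _design(X, lay, clamp=True)
        self._pirls(M, yb, self.ridge)
        if (not self.converged_) or np.abs(self.coef_).max() > _COEF_BLOWUP:
            warnings.warn(
                "possible complete separation or non-convergence; "
                f"refitting with stabilizing ridge {self.separation_ridge}",
                stacklevel=2,
            )
            self._pirls(M, yb, self.separation_ridge)
            self.stabilized_ = True
        else:
            self.stabilized_ = False
        self._finalize(M, yb)
        return self

    def _pirls(self, M, y, ridge):
        lay = self.layout_
        P = _penalty(lay, self.lam, ridge)
        beta = np.zeros(lay.n_coef)
        p0 = np.clip(y.mean(), _PROB_CLIP, 1 - _PROB_CLIP)
        beta[0] = np.log(p0 / (1 - p0))

        def pdev(b):
            mu = 1.0 / (1.0 + np.exp(-(M @ b)))
            return _bernoulli_deviance(y, mu) + float(b @ P @ b)

        current = pdev(beta)
        trace = [current]
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = M @ beta
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _PROB_CLIP, 1 - _PROB_CLIP)
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            MtW = M.T * w
            A = MtW @ M + P
            try:
                proposal = linalg.solve(A, MtW @ z, assume_a="pos")
            except linalg.LinAlgError:
                proposal = np.linalg.lstsq(A, MtW @ z, rcond=None)[0]
            # step-halving: the accepted step never increases the objective
            step, new = proposal, pdev(proposal)
            halvings = 0
            while new > current + 1e-12 and halvings < 30:
                step = 0.5 * (step + beta)
                new = pdev(step)
                halvings += 1
            beta = step
            trace.append(new)
            if abs(current - new) <= self.tol * (abs(new) + 0.1):
                converged = True
                current = new
                break
            current = new

        self.coef_ = beta
        self.intercept_ = float(beta[0])
        self.converged_ = converged
        self.n_iter_ = len(trace) - 1
        self.ridge_used_ = ridge
        self.penalized_deviance_ = float(current)
        self.deviance_trace_ = np.array(trace)
        self._penalty_ = P

    def _finalize(self, M, y):
        eta = M @ self.coef_
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _PROB_CLIP, 1 - _PROB_CLIP)
        self.fitted_values_ = mu
        self.deviance_ = float(_bernoulli_deviance(y, mu))
        # effective degrees of freedom per smooth: trace of the block of
        # (M'WM + P)^-1 M'WM belonging to that term
        w = mu * (1 - mu)
        MtWM = (M.T * w) @ M
        try:
            H = linalg.solve(MtWM + self._penalty_, MtWM, assume_a="pos")
        except linalg.LinAlgError:
            H = np.linalg.lstsq(MtWM + self._penalty_, MtWM, rcond=None)[0]
        self.edf_ = {
            var: float(np.trace(H[s, s]))
            for var, s in self.layout_.slices.items()
        }

    # -- prediction -------------------------------------------------------
    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        M = _design(X, self.layout_, clamp=self.clamp)
        return M @ self.coef_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    # -- interpretation ---------------------------------------------------
    def partial_effect(
        self, variable: str, grid_size: int = 100, x_range=None
    ) -> PartialEffectCurve:
        """Centered smooth effect f(x) on a grid spanning the training range
        (or an explicit ``x_range`` in fit-scale units)."""
        lay = self.layout_
        if variable not in lay.numeric_terms:
            raise ValueError(
                f"{variable!r} is not a continuous model term "
                "(use state_estimates for categorical terms)"
            )
        spec = lay.specs[variable]
        lo, hi = spec.boundary if x_range is None else map(float, x_range)
        grid = np.linspace(lo, hi, grid_size)
        B = build_basis(grid, spec) - lay.centers[variable]
        return PartialEffectCurve(
            variable=variable, x=grid, values=B @ self.coef_[lay.slices[variable]]
        )

    def state_estimates(self, variable: str) -> dict:
        """Per-state coefficients (log-odds) under the sum-to-zero coding."""
        lay = self.layout_
        if variable not in lay.categorical_terms:
            raise ValueError(f"{variable!r} is not a categorical model term")
        vals = lay.contrasts[variable] @ self.coef_[lay.slices[variable]]
        return dict(zip(lay.levels[variable], map(float, vals)))

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "model": "pspline-logistic-gam",
                "lam": self.lam,
                "ridge_used": self.ridge_used_,
                "coef": self.coef_.tolist(),
                "classes": np.asarray(self.classes_).tolist(),
                "layout": self.layout_.to_dict(),
                "clamp": self.clamp,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, source) -> "PSplineLogisticGAM":
        if hasattr(source, "read"):
            d = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        lay = TermLayout.from_dict(d["layout"])
        est = cls(lam=d["lam"], layout=lay, clamp=d.get("clamp", True))
        est.layout_ = lay
        est.coef_ = np.array(d["coef"])
        est.intercept_ = float(est.coef_[0])
        est.classes_ = np.array(d["classes"])
        est.ridge_used_ = d["ridge_used"]
        return est
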