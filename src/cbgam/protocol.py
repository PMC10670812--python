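"""Model-development protocol: from a validated cohort to a bootstrap-
averaged penalized logistic GAM with interpretable outputs.

The five steps:

1. **Correlation filtering** — pairwise association (Pearson |r| for
   continuous pairs, Cramer's V for categorical pairs, max one-hot |r| for
   mixed pairs); from each pair above the threshold the lower-priority
   variable is removed greedily until no pair exceeds the threshold.
2. **Standardization** — z-scoring of the continuous candidates with the
   full-cohort mean/sd recorded for exact inversion (cutoffs are reported
   back in raw units).
3. **Hyperparameter grid search** — for every (n_splines, lambda) cell,
   stratified-bootstrap fits scored by mean out-of-bag AUC; ties break
   toward fewer splines, then larger lambda (parsimony).
4. **Ensemble estimation** — many stratified-bootstrap refits with the
   spline bases frozen from the full cohort, so per-iteration coefficients
   live in a shared basis.
5. **Averaging** — the ensemble model's coefficients are the arithmetic
   mean of the per-iteration coefficients.

Plus the two interpretation outputs: bootstrap-averaged per-state estimates
of dichotomized categorical predictors, and detection of the raw-unit
cutoff beyond which a smooth's influence becomes negligible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from .descriptives import chi_squared_test
from .gam import PSplineLogisticGAM, PartialEffectCurve, TermLayout, build_layout

logger = logging.getLogger("cbgam.protocol")

__all__ = [
    "ProtocolConfig",
    "Standardizer",
    "CutoffResult",
    "CategoricalStateEstimate",
    "association_matrix",
    "correlation_filter",
    "standardize_features",
    "stratified_bootstrap",
    "grid_search",
    "BootstrapGAMEnsemble",
    "categorical_state_estimate",
    "detect_cutoff",
    "develop_model",
]


@dataclass
class ProtocolConfig:
    """Configuration of the five-step development protocol."""

    candidates_continuous: tuple = ("age", "bmi", "pt_volume", "mtv", "tlg")
    candidates_categorical: tuple = ("t_stage", "m_stage")
    correlation_threshold: float = 0.8
    keep_priority: tuple = ("pt_volume", "tlg", "suv_max", "suv_mean", "mtv")
    n_splines_grid: tuple = (8, 12, 16, 20)
    lambda_grid: tuple = tuple(float(10.0**k) for k in range(-2, 4))
    B_tune: int = 50
    B_estimate: int = 10000
    seed: int = 0
    ridge: float = 0.2             # per-fit L2 stabilizer for bootstrap bags
    epsilon: float = 0.05          # negligible-influence tolerance (x range)
    cutoff_grid_size: int = 200
    cutoff_grid_quantile: float = 0.95  # curve support used for cutoff search
    cutoff_variables: tuple = ("pt_volume", "tlg")
    dichotomizations: tuple = (
        ("t_stage", (("1", (1,)), (">1", (2, 3, 4)))),
        ("m_stage", (("0", (0,)), ("1", (1,)))),
    )

    def __post_init__(self):
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.B_tune < 1 or self.B_estimate < 1:
            raise ValueError("bootstrap iteration counts must be >= 1")
        if not self.n_splines_grid or not self.lambda_grid:
            raise ValueError("hyperparameter grid must be non-empty")

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["dichotomizations"] = [
            [var, [[lab, list(states)] for lab, states in groups]]
            for var, groups in self.dichotomizations
        ]
        doc = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_yaml(cls, source) -> "ProtocolConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        for key in (
            "candidates_continuous", "candidates_categorical", "keep_priority",
            "n_splines_grid", "lambda_grid", "cutoff_variables",
        ):
            if key in d:
                d[key] = tuple(d[key])
        if "dichotomizations" in d:
            d["dichotomizations"] = tuple(
                (var, tuple((lab, tuple(states)) for lab, states in groups))
                for var, groups in d["dichotomizations"]
            )
        return cls(**d)


# ---------------------------------------------------------------------------
# step 1: correlation filtering
# ---------------------------------------------------------------------------

def _cramers_v(a, b) -> float:
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi2, _, _ = chi_squared_test(tab)
    n = tab.sum()
    return float(np.sqrt(chi2 / (n * (min(tab.shape) - 1))))


def _mixed_assoc(x_cont, x_cat) -> float:
    """Max |Pearson r| between the continuous variable and the one-hot
    indicators of the categorical one."""
    best = 0.0
    for lv in pd.unique(x_cat):
        ind = (np.asarray(x_cat) == lv).astype(float)
        if ind.std() == 0:
            continue
        best = max(best, abs(float(np.corrcoef(x_cont, ind)[0, 1])))
    return best


def association_matrix(df: pd.DataFrame, continuous, categorical) -> pd.DataFrame:
    """Symmetric |association| matrix over mixed-type candidate variables."""
    names = list(continuous) + list(categorical)
    is_cont = {v: v in set(continuous) for v in names}
    A = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if is_cont[a] and is_cont[b]:
                r = abs(float(np.corrcoef(df[a], df[b])[0, 1]))
            elif not is_cont[a] and not is_cont[b]:
                r = _cramers_v(df[a], df[b])
            else:
                cont, cat = (a, b) if is_cont[a] else (b, a)
                r = _mixed_assoc(df[cont].to_numpy(dtype=float), df[cat])
            A.loc[a, b] = A.loc[b, a] = r
    return A


@dataclass
class FilterResult:
    kept_continuous: list
    kept_categorical: list
    dropped: list                 # (variable, partner, association)
    matrix: pd.DataFrame


def correlation_filter(
    df: pd.DataFrame,
    continuous,
    categorical,
    threshold: float = 0.8,
    keep_priority=(),
) -> FilterResult:
    """Greedily remove the lower-priority member of each over-threshold pair.

    Variables named earlier in ``keep_priority`` win; unlisted variables rank
    after listed ones, ties broken by candidate order.  Constant variables
    are dropped up front with a warning.
    """
    continuous, categorical = list(continuous), list(categorical)
    dropped = []
    for var in list(continuous):
        if df[var].nunique() <= 1:
            warnings.warn(f"constant variable {var!r} dropped", stacklevel=2)
            continuous.remove(var)
            dropped.append((var, None, np.nan))
    names = continuous + categorical
    prio = {v: i for i, v in enumerate(keep_priority)}
    order = {v: i for i, v in enumerate(names)}
    A = association_matrix(df, continuous, categorical)

    def rank(v):  # smaller = keep
        return (prio.get(v, len(prio)), order[v])

    active = set(names)
    while True:
        best = None
        for i, a in enumerate(names):
            if a not in active:
                continue
            for b in names[i + 1:]:
                if b not in active:
                    continue
                r = A.loc[a, b]
                if r >= threshold and (best is None or r > best[2]):
                    best = (a, b, r)
        if best is None:
            break
        a, b, r = best
        loser = b if rank(a) < rank(b) else a
        winner = a if loser == b else b
        active.remove(loser)
        dropped.append((loser, winner, float(r)))
        logger.info("correlation filter: dropped %s (|assoc|=%.3f with %s)",
                    loser, r, winner)
    return FilterResult(
        kept_continuous=[v for v in continuous if v in active],
        kept_categorical=[v for v in categorical if v in active],
        dropped=dropped,
        matrix=A,
    )


# ---------------------------------------------------------------------------
# step 2: standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-variable z-score transform with exact inversion."""

    means: dict
    sds: dict

    @classmethod
    def fit(cls, df: pd.DataFrame, variables) -> "Standardizer":
        means, sds = {}, {}
        for var in variables:
            x = df[var].to_numpy(dtype=float)
            m, s = float(x.mean()), float(x.std())  # population sd (ddof=0)
            if s == 0:
                raise ValueError(f"zero variance: cannot standardize {var!r}")
            means[var], sds[var] = m, s
        return cls(means, sds)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for var in self.means:
            out[var] = (df[var].to_numpy(dtype=float) - self.means[var]) / self.sds[var]
        return out

    def to_raw(self, variable: str, z):
        return self.means[variable] + self.sds[variable] * np.asarray(z, dtype=float)

    def to_standardized(self, variable: str, x):
        return (np.asarray(x, dtype=float) - self.means[variable]) / self.sds[variable]


def standardize_features(df: pd.DataFrame, variables):
    """Z-score ``variables`` with full-cohort moments; returns (frame, record)."""
    std = Standardizer.fit(df, variables)
    return std.transform(df), std


# ---------------------------------------------------------------------------
# step 3: stratified bootstrap + grid search
# ---------------------------------------------------------------------------

def stratified_bootstrap(y, seed):
    """One stratified bootstrap split: per-stratum sampling with replacement.

    Returns (bag_indices, out_of_bag_indices); the bag holds exactly
    n_stratum draws per stratum, so the bag class balance equals the
    cohort's.  ``seed`` may be an int or a numpy Generator.
    """
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bag = []
    for value in np.unique(y):
        idx = np.flatnonzero(y == value)
        if len(idx) == 0:
            raise ValueError("empty stratum")
        bag.append(rng.choice(idx, size=len(idx), replace=True))
    bag = np.concatenate(bag)
    oob = np.setdiff1d(np.arange(len(y)), bag)
    return bag, oob


def _oob_auc(model, X, y, bag, oob):
    if len(oob) == 0 or len(np.unique(np.asarray(y)[oob])) < 2:
        return np.nan
    scores = model.predict_proba(X.iloc[oob])[:, 1]
    return float(roc_auc_score(np.asarray(y)[oob], scores))


@dataclass
class GridSearchResult:
    n_splines: int
    lam: float
    table: pd.DataFrame  # n_splines, lam, mean_oob_auc, n_valid


def grid_search(
    X: pd.DataFrame,
    y,
    numeric_terms,
    categorical_terms,
    n_splines_grid,
    lambda_grid,
    B_tune: int = 50,
    seed: int = 0,
    **gam_kwargs,
) -> GridSearchResult:
    """Exhaustive (n_splines, lambda) search by mean out-of-bag AUC.

    Common random numbers: every cell sees the same B_tune bootstrap splits.
    Ties break toward smaller n_splines, then larger lambda.
    """
    y = np.asarray(y)
    seeds = np.random.SeedSequence(seed).spawn(B_tune)
    splits = [
        stratified_bootstrap(y, np.random.default_rng(s)) for s in seeds
    ]
    layouts = {
        k: build_layout(X, numeric_terms, categorical_terms, k,
                        gam_kwargs.get("degree", 3))
        for k in n_splines_grid
    }
    rows = []
    for k in n_splines_grid:
        for lam in lambda_grid:
            aucs = []
            for bag, oob in splits:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m = PSplineLogisticGAM(
                            n_splines=k, lam=lam, layout=layouts[k], **gam_kwargs
                        ).fit(X.iloc[bag], y[bag])
                    aucs.append(_oob_auc(m, X, y, bag, oob))
                except Exception as exc:  # cell iteration failed to fit
                    logger.warning("grid cell (%d, %g) iteration failed: %s",
                                   k, lam, exc)
                    aucs.append(np.nan)
            aucs = np.array(aucs)
            valid = np.isfinite(aucs)
            rows.append({
                "n_splines": k,
                "lam": lam,
                "mean_oob_auc": float(np.nanmean(aucs)) if valid.any() else np.nan,
                "n_valid": int(valid.sum()),
            })
    table = pd.DataFrame(rows)
    usable = table[table["n_valid"] > 0]
    if usable.empty:
        raise RuntimeError("every grid cell failed to fit")
    best = usable.sort_values(
        ["mean_oob_auc", "n_splines", "lam"], ascending=[False, True, False]
    ).iloc[0]
    return GridSearchResult(int(best["n_splines"]), float(best["lam"]), table)


# ---------------------------------------------------------------------------
# steps 4-5: ensemble estimation and averaging
# ---------------------------------------------------------------------------

class BootstrapGAMEnsemble(BaseEstimator):
    """Stratified-bootstrap ensemble of P-spline logistic GAMs.

    Fits ``B`` models on stratified bootstrap resamples with the basis
    layout frozen from the full data, stores every iteration's coefficient
    vector and out-of-bag AUC, and exposes the coefficient-averaged model
    as ``avg_model_``.  Iterations that fail to fit are skipped (more than
    ``max_failure_rate`` failures is an error).
    """

    def __init__(
        self,
        numeric_terms=None,
        categorical_terms=None,
        n_splines: int = 8,
        degree: int = 3,
        lam: float = 1.0,
        B: int = 10000,
        seed: int = 0,
        ridge: float = 0.2,
        separation_ridge: float = 0.1,
        max_failure_rate: float = 0.05,
    ):
        self.numeric_terms = numeric_terms
        self.categorical_terms = categorical_terms
        self.n_splines = n_splines
        self.degree = degree
        self.lam = lam
        self.B = B
        self.seed = seed
        self.ridge = ridge
        self.separation_ridge = separation_ridge
        self.max_failure_rate = max_failure_rate

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        num = list(self.numeric_terms or [])
        cat = list(self.categorical_terms or [])
        if not num and not cat:
            num = [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])]
            cat = [c for c in X.columns if c not in num]
        layout = build_layout(X, num, cat, self.n_splines, self.degree)
        self.layout_ = layout

        seeds = np.random.SeedSequence(self.seed).spawn(self.B)
        coefs, aucs, n_stab, failures = [], [], 0, 0
        for i, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            bag, oob = stratified_bootstrap(y, rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = PSplineLogisticGAM(
                        n_splines=self.n_splines, degree=self.degree,
                        lam=self.lam, ridge=self.ridge,
                        separation_ridge=self.separation_ridge, layout=layout,
                    ).fit(X.iloc[bag], y[bag])
            except Exception as exc:
                failures += 1
                logger.warning("ensemble iteration %d skipped: %s", i, exc)
                continue
            coefs.append(m.coef_)
            aucs.append(_oob_auc(m, X, y, bag, oob))
            n_stab += int(m.stabilized_)
        if failures > self.max_failure_rate * self.B:
            raise RuntimeError(
                f"{failures}/{self.B} ensemble iterations failed "
                f"(> {self.max_failure_rate:.0%})"
            )

        self.coef_samples_ = np.array(coefs)
        self.oob_auc_ = np.array(aucs)
        valid = np.isfinite(self.oob_auc_)
        self.oob_auc_mean_ = float(np.nanmean(self.oob_auc_)) if valid.any() else np.nan
        self.oob_auc_sd_ = (
            float(np.nanstd(self.oob_auc_, ddof=1)) if valid.sum() > 1 else np.nan
        )
        self.n_failed_ = failures
        self.n_stabilized_ = n_stab
        self.coef_ = self.coef_samples_.mean(axis=0)

        avg = PSplineLogisticGAM(
            n_splines=self.n_splines, degree=self.degree, lam=self.lam,
            layout=layout,
        )
        avg.layout_ = layout
        avg.coef_ = self.coef_
        avg.intercept_ = float(self.coef_[0])
        avg.classes_ = self.classes_
        avg.ridge_used_ = self.ridge
        self.avg_model_ = avg
        # keep references for downstream interpretation steps
        self._X, self._y = X, y
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.avg_model_.predict_proba(X)

    def predict(self, X: pd.DataFrame):
        return self.avg_model_.predict(X)

    def partial_effect(
        self, variable: str, grid_size: int = 100, x_range=None
    ) -> PartialEffectCurve:
        """Averaged-model smooth with pointwise sd across ensemble members."""
        curve = self.avg_model_.partial_effect(variable, grid_size, x_range=x_range)
        lay = self.layout_
        from .basis import build_basis  # local to avoid cycle at import time

        B = build_basis(curve.x, lay.specs[variable]) - lay.centers[variable]
        samples = self.coef_samples_[:, lay.slices[variable]] @ B.T
        curve.spread = samples.std(axis=0, ddof=1)
        return curve

    def state_estimates(self, variable: str) -> dict:
        return self.avg_model_.state_estimates(variable)


# ---------------------------------------------------------------------------
# interpretation: per-state categorical estimates and cutoff detection
# ---------------------------------------------------------------------------

@dataclass
class CategoricalStateEstimate:
    variable: str
    dichotomization: dict          # original state -> group label
    estimates: dict                # group label -> averaged log-odds estimate
    weights: dict                  # group label -> frequency weight


def categorical_state_estimate(
    X: pd.DataFrame,
    y,
    variable: str,
    groups,
    n_splines: int,
    lam: float,
    B: int,
    seed: int = 0,
    numeric_terms=None,
    categorical_terms=None,
    **ensemble_kwargs,
) -> CategoricalStateEstimate:
    """Bootstrap-averaged per-state influence of a dichotomized predictor.

    ``groups`` maps each of two group labels to the original states pooled
    into it, e.g. ``{"1": (1,), ">1": (2, 3, 4)}``.  The variable is recoded
    *before* fitting and the ensemble refit with the same protocol; the
    reported estimates are the averaged per-state coefficients under the
    frequency-weighted sum-to-zero coding (they satisfy
    sum_s w_s * estimate_s = 0).
    """
    groups = dict(groups)
    if len(groups) != 2:
        raise ValueError("dichotomization must define exactly 2 groups")
    mapping = {}
    for label, states in groups.items():
        for s in states:
            mapping[s] = label
    present = set(pd.unique(X[variable]))
    missing = present - set(mapping)
    if missing:
        raise ValueError(f"states {sorted(missing)} not covered by dichotomization")
    uncovered = [s for s in mapping if s not in present]
    if uncovered:
        raise ValueError(f"states {uncovered} absent from the cohort")

    X2 = X.copy()
    X2[variable] = X[variable].map(mapping)
    cat = list(categorical_terms) if categorical_terms is not None else None
    ens = BootstrapGAMEnsemble(
        numeric_terms=numeric_terms, categorical_terms=cat,
        n_splines=n_splines, lam=lam, B=B, seed=seed, **ensemble_kwargs,
    ).fit(X2, y)
    est = ens.state_estimates(variable)
    w = dict(zip(ens.layout_.levels[variable],
                 map(float, ens.layout_.weights[variable])))
    return CategoricalStateEstimate(
        variable=variable,
        dichotomization={str(k): v for k, v in mapping.items()},
        estimates=est,
        weights=w,
    )


@dataclass
class CutoffResult:
    """Raw/standardized covariate value beyond which a smooth is negligible."""

    variable: str
    cutoff_raw: float | None
    cutoff_std: float | None
    found: bool
    negligible_everywhere: bool


def detect_cutoff(
    curve: PartialEffectCurve,
    epsilon: float = 0.05,
    standardizer: Standardizer | None = None,
) -> CutoffResult:
    """Smallest grid value x* with |f(x) - f(x_max)| <= eps * range(f) for
    all x >= x*.

    x* at the first grid point means the effect is negligible everywhere.
    A genuine plateau must also be longer than the trailing sliver that any
    strictly monotone curve produces (a linear effect sits within the
    terminal eps-band over the last eps fraction of its span): the
    detected plateau must cover at least 2*eps of the grid span, otherwise
    "no cutoff found".  A flat curve is negligible everywhere.
    """
    if len(curve.x) < 50:
        raise ValueError("cutoff detection needs a grid of >= 50 points")
    f = curve.values
    rng = float(f.max() - f.min())
    raw_grid = curve.x_raw
    if raw_grid is None and standardizer is not None:
        raw_grid = standardizer.to_raw(curve.variable, curve.x)

    def result(i, found, negligible):
        if not found:
            return CutoffResult(curve.variable, None, None, False, False)
        x_std = float(curve.x[i])
        x_raw = float(raw_grid[i]) if raw_grid is not None else x_std
        return CutoffResult(curve.variable, x_raw, x_std, True, negligible)

    if rng == 0.0:
        return result(0, True, True)
    dev = np.abs(f - f[-1])
    ok = dev <= epsilon * rng
    # smallest index from which the tail is all-ok
    bad = np.flatnonzero(~ok)
    i = 0 if len(bad) == 0 else int(bad[-1]) + 1
    if i == 0:
        return result(0, True, True)
    span = curve.x[-1] - curve.x[0]
    plateau = curve.x[-1] - curve.x[i] if i < len(f) else 0.0
    if i >= len(f) - 1 or plateau < 2 * epsilon * span:
        return result(None, False, False)
    return result(i, True, False)


# ---------------------------------------------------------------------------
# orchestration: the full protocol
# ---------------------------------------------------------------------------

@dataclass
class DevelopmentResult:
    config: ProtocolConfig
    filter: FilterResult
    standardizer: Standardizer
    hyperparams: GridSearchResult
    ensemble: BootstrapGAMEnsemble
    curves: dict                    # variable -> PartialEffectCurve (raw grid)
    cutoffs: dict                   # variable -> CutoffResult
    state_estimates: dict           # variable -> CategoricalStateEstimate

    def report(self) -> dict:
        return {
            "kept_continuous": self.filter.kept_continuous,
            "kept_categorical": self.filter.kept_categorical,
            "dropped": [
                {"variable": v, "partner": p,
                 "association": None if a != a else float(a)}
                for v, p, a in self.filter.dropped
            ],
            "n_splines": self.hyperparams.n_splines,
            "lambda": self.hyperparams.lam,
            "B": int(self.ensemble.B),
            "oob_auc_mean": self.ensemble.oob_auc_mean_,
            "oob_auc_sd": self.ensemble.oob_auc_sd_,
            "n_failed_iterations": self.ensemble.n_failed_,
            "n_stabilized_iterations": self.ensemble.n_stabilized_,
            "cutoffs": {
                v: dataclasses.asdict(c) for v, c in self.cutoffs.items()
            },
            "state_estimates": {
                v: {"estimates": e.estimates, "weights": e.weights}
                for v, e in self.state_estimates.items()
            },
        }

    def report_json(self, path=None) -> str:
        doc = json.dumps(self.report(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


def develop_model(
    cohort: pd.DataFrame,
    config: ProtocolConfig | None = None,
    reps_scale: float = 1.0,
) -> DevelopmentResult:
    """Run the full five-step protocol on a cohort with a derived ``cb``.

    ``reps_scale`` proportionally scales B_tune and B_estimate (desk-scale
    runs); hyperparameter selection happens once, then stays fixed for all
    estimation iterations.
    """
    cfg = config or ProtocolConfig()
    if "cb" not in cohort.columns:
        from .cohort import attach_cb

        cohort = attach_cb(cohort)
    y = cohort["cb"].to_numpy()
    b_tune = max(1, int(round(cfg.B_tune * reps_scale)))
    b_est = max(1, int(round(cfg.B_estimate * reps_scale)))
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)

    filt = correlation_filter(
        cohort,
        cfg.candidates_continuous,
        cfg.candidates_categorical,
        threshold=cfg.correlation_threshold,
        keep_priority=cfg.keep_priority,
    )
    logger.info("kept: %s + %s", filt.kept_continuous, filt.kept_categorical)

    std_df, std = standardize_features(cohort, filt.kept_continuous)
    X = std_df[filt.kept_continuous + filt.kept_categorical]

    gs = grid_search(
        X, y, filt.kept_continuous, filt.kept_categorical,
        cfg.n_splines_grid, cfg.lambda_grid, B_tune=b_tune,
        seed=int(seeds[0].generate_state(1)[0] % 2**31), ridge=cfg.ridge,
    )
    logger.info("chosen hyperparameters: n_splines=%d lambda=%g",
                gs.n_splines, gs.lam)

    ens = BootstrapGAMEnsemble(
        numeric_terms=filt.kept_continuous,
        categorical_terms=filt.kept_categorical,
        n_splines=gs.n_splines, lam=gs.lam, B=b_est, ridge=cfg.ridge,
        seed=int(seeds[1].generate_state(1)[0] % 2**31),
    ).fit(X, y)

    curves, cutoffs = {}, {}
    for var in filt.kept_continuous:
        curve = ens.partial_effect(var, grid_size=cfg.cutoff_grid_size)
        curve.x_raw = std.to_raw(var, curve.x)
        curves[var] = curve
        if var in cfg.cutoff_variables:
            # cutoff search is confined to the well-supported covariate range:
            # beyond the upper quantile the smooth is extrapolation-dominated
            # and a level comparison against it is meaningless
            hi = float(np.quantile(X[var], cfg.cutoff_grid_quantile))
            lo = float(X[var].min())
            trimmed = ens.partial_effect(
                var, grid_size=cfg.cutoff_grid_size, x_range=(lo, hi)
            )
            trimmed.x_raw = std.to_raw(var, trimmed.x)
            cutoffs[var] = detect_cutoff(trimmed, epsilon=cfg.epsilon)

    estimates = {}
    for j, (var, groups) in enumerate(cfg.dichotomizations):
        if var not in filt.kept_categorical:
            continue
        estimates[var] = categorical_state_estimate(
            X, y, var, dict(groups), n_splines=gs.n_splines, lam=gs.lam,
            B=b_est, seed=int(seeds[2].generate_state(2)[j] % 2**31),
            ridge=cfg.ridge, numeric_terms=filt.kept_continuous,
            categorical_terms=filt.kept_categorical,
        )

    return DevelopmentResult(
        config=cfg, filter=filt, standardizer=std, hyperparams=gs,
        ensemble=ens, curves=curves, cutoffs=cutoffs, state_estimates=estimates,
    )
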