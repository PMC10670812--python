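"""Penalized logistic GAM: closed forms, optimization oracles, limiting
cases, centering, effective degrees of freedom, serialization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import cbgam
from cbgam.gam import PSplineLogisticGAM, _design, _penalty


def _toy(n=200, seed=0, hard=False):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2, 2, n)
    lp = 2.0 * np.sin(1.2 * x) if hard else 1.5 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return pd.DataFrame({"x": x}), y


def brute_force_fit(X, y, model):
    """Numerically maximize the identical penalized likelihood (oracle)."""
    M = _design(X, model.layout_)
    P = _penalty(model.layout_, model.lam, model.ridge_used_)

    def obj(b):
        eta = M @ b
        mu = 1 / (1 + np.exp(-np.clip(eta, -35, 35)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        return -ll + 0.5 * b @ P @ b

    res = optimize.minimize(
        obj, np.zeros(M.shape[1]), method="BFGS",
        options={"gtol": 1e-12, "maxiter": 10000},
    )
    return res.x


def test_intercept_only_closed_form():
    y = np.array([1] * 14 + [0] * 6)
    X = pd.DataFrame(index=range(20))
    m = PSplineLogisticGAM(numeric_terms=[], categorical_terms=[]).fit(X, y)
    assert m.intercept_ == pytest.approx(np.log(0.7 / 0.3), abs=1e-8)


def test_matches_direct_optimization_oracle():
    X, y = _toy(n=40, seed=3, hard=True)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=[], n_splines=6, lam=0.0
    ).fit(X, y)
    assert np.abs(brute_force_fit(X, y, m) - m.coef_).max() < 1e-5


def test_penalized_oracle_with_categorical_term():
    X, y = _toy(n=50, seed=5, hard=True)
    X["g"] = np.where(np.arange(50) % 3 == 0, "a", "b")
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=["g"], n_splines=8, lam=2.5
    ).fit(X, y)
    assert np.abs(brute_force_fit(X, y, m) - m.coef_).max() < 1e-5


def test_high_lambda_collapses_to_linear_logit():
    import statsmodels.api as sm

    X, y = _toy(n=300, seed=1)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=[], n_splines=10, lam=1e8
    ).fit(X, y)
    glm = sm.GLM(y, sm.add_constant(X.x), family=sm.families.Binomial()).fit()
    p_lin = np.asarray(glm.predict(sm.add_constant(X.x)))
    assert np.abs(m.predict_proba(X)[:, 1] - p_lin).max() < 1e-3


def test_prediction_reproduces_fitted_values():
    X, y = _toy(n=150, seed=2, hard=True)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=[], n_splines=8, lam=1.0
    ).fit(X, y)
    assert np.abs(m.predict_proba(X)[:, 1] - m.fitted_values_).max() < 1e-10
    # additive predictor 0 -> probability exactly 0.5
    m.coef_ = np.zeros_like(m.coef_)
    assert m.predict_proba(X)[:, 1] == pytest.approx(0.5)


def test_monotone_signal_gives_monotone_smooth():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 4, 800)
    y = (rng.random(800) < 1 / (1 + np.exp(-(x - 2) * 2.0))).astype(int)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=[], n_splines=8, lam=100.0
    ).fit(pd.DataFrame({"x": x}), y)
    curve = m.partial_effect("x", grid_size=80)
    assert (np.diff(curve.values) > -1e-6).all()


def test_smooths_centered_over_training_sample():
    X, y = _toy(n=200, seed=6, hard=True)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=[], n_splines=8, lam=1.0
    ).fit(X, y)
    from cbgam.basis import build_basis

    lay = m.layout_
    B = build_basis(X.x.to_numpy(), lay.specs["x"]) - lay.centers["x"]
    contrib = B @ m.coef_[lay.slices["x"]]
    assert abs(contrib.mean()) < 1e-8


def test_null_effect_curve_is_flat():
    X, y = _toy(n=100, seed=7)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=[], n_splines=6, lam=1.0
    ).fit(X, y)
    lay = m.layout_
    m.coef_[lay.slices["x"]] = 3.14  # equal coefficients = constant smooth
    curve = m.partial_effect("x")
    assert np.abs(curve.values).max() < 1e-9


def test_penalized_deviance_nonincreasing():
    X, y = _toy(n=300, seed=8, hard=True)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=[], n_splines=10, lam=0.1
    ).fit(X, y)
    assert (np.diff(m.deviance_trace_) <= 1e-9).all()


def test_edf_nonincreasing_in_lambda():
    X, y = _toy(n=400, seed=9, hard=True)
    edfs = []
    for lam in (0.01, 1.0, 100.0, 10000.0):
        m = PSplineLogisticGAM(
            numeric_terms=["x"], categorical_terms=[], n_splines=10, lam=lam
        ).fit(X, y)
        edfs.append(m.edf_["x"])
    assert (np.diff(edfs) <= 1e-3).all()
    assert edfs[-1] < 2.5  # high-lambda smooth ~ linear (about 2 dof)


def test_categorical_sum_to_zero_and_unseen_state():
    X, y = _toy(n=120, seed=10)
    X["g"] = np.tile(["a", "b", "c"], 40)
    m = PSplineLogisticGAM(
        numeric_terms=["x"], categorical_terms=["g"], n_splines=6, lam=1.0
    ).fit(X, y)
    est = m.state_estimates("g")
    w = m.layout_.weights["g"]
    assert abs(sum(w[i] * est[lv] for i, lv in enumerate(["a", "b", "c"]))) < 1e-10
    bad = X.copy()
    bad["g"] = "zzz"
    with pytest.raises(ValueError, match="unseen"):
        m.predict_proba(bad)


def test_separation_triggers_stabilized_refit():
    x = np.linspace(-1, 1, 40)
    y = (x > 0).astype(int)
    with pytest.warns(UserWarning, match="separation|ridge"):
        m = PSplineLogisticGAM(
            numeric_terms=["x"], categorical_terms=[], n_splines=6, lam=0.01
        ).fit(pd.DataFrame({"x": x}), y)
    assert m.stabilized_
    assert np.abs(m.coef_).max() < 30


def test_single_class_y_rejected():
    X, _ = _toy(n=30)
    with pytest.raises(ValueError, match="two classes"):
        PSplineLogisticGAM(numeric_terms=["x"], categorical_terms=[]).fit(
            X, np.ones(30)
        )


def test_json_round_trip_reproduces_predictions(tmp_path, cohort70):
    from cbgam.protocol import standardize_features

    sdf, _ = standardize_features(cohort70, ["age", "pt_volume"])
    X = sdf[["age", "pt_volume", "m_stage"]]
    y = cohort70.cb.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = PSplineLogisticGAM(
            numeric_terms=["age", "pt_volume"], categorical_terms=["m_stage"],
            n_splines=6, lam=10.0,
        ).fit(X, y)
    path = tmp_path / "model.json"
    m.to_json(path)
    back = cbgam.PSplineLogisticGAM.from_json(path)
    np.testing.assert_array_equal(
        m.predict_proba(X), back.predict_proba(X)
    )


def test_sklearn_clone_and_params():
    from sklearn.base import clone

    m = PSplineLogisticGAM(n_splines=7, lam=3.0)
    c = clone(m)
    assert c.get_params()["n_splines"] == 7 and c.get_params()["lam"] == 3.0
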