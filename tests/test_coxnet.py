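"""Weighted elastic-net Cox solver against independent oracles."""
import numpy as np
import pandas as pd
import pytest

from mbcrs.coxnet import (CoxnetRiskScore, ElasticNetConfig, breslow_loglik,
                          cross_validate_lambda, kkt_violation, _standardize,
                          weighted_coxnet_path)

from oracles import cox_loglik_brute, cox_newton_brute


def test_loglik_matches_brute_force(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    rng = np.random.default_rng(0)
    beta = rng.normal(size=X.shape[1])
    ll = breslow_loglik(entry, stop, event, w, X @ beta)
    ll_brute = cox_loglik_brute(beta, X, entry, stop, event, w)
    assert ll == pytest.approx(ll_brute, abs=1e-9)


def test_unpenalized_fit_matches_newton_oracle(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    m = CoxnetRiskScore(cv=0, lambda_fixed=0.0, tol=1e-9).fit(
        X, (event, stop), sample_weight=w, entry=entry)
    oracle = cox_newton_brute(X, entry, stop, event, w)
    assert np.abs(m.coef_ - oracle).max() < 1e-4


def test_ridge_fit_matches_penalized_newton_oracle(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    lam = 0.08
    v = w / w.sum()
    Xs, _, _ = _standardize(X, v, True)
    Xs = np.asarray(Xs)
    m = CoxnetRiskScore(alpha=0.0, cv=0, lambda_fixed=lam, tol=1e-9,
                        standardize=False).fit(
        Xs, (event, stop), sample_weight=w, entry=entry)
    oracle = cox_newton_brute(Xs, entry, stop, event, w, ridge=lam)
    assert np.abs(m.coef_ - oracle).max() < 1e-4


def test_lambda_above_lambda_max_gives_null_model(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    cfg = ElasticNetConfig(alpha=0.5, n_lambdas=5)
    path = weighted_coxnet_path(X, (entry, stop, event), w, cfg)
    big = ElasticNetConfig(alpha=0.5,
                           lambda_path=[path["lambda_max"] * 2.0])
    out = weighted_coxnet_path(X, (entry, stop, event), w, big)
    assert np.all(out["coefs"] == 0.0)


def test_path_matches_glmnet_reference():
    """Coefficient path vs values computed with the glmnet R package on the
    identical fixture (weighted Cox, alpha 0.5, standardize=TRUE)."""
    rng = np.random.default_rng(42)
    n, p = 300, 10
    X = rng.normal(size=(n, p))
    beta = np.array([0.5, -0.4, 0.3, 0, 0, 0, 0, 0, 0, 0.0])
    T = rng.exponential(1 / (0.1 * np.exp(X @ beta)))
    C = rng.exponential(8, n)
    stop = np.minimum(T, C)
    event = (T <= C).astype(int)
    w = rng.uniform(0.5, 2.0, n)
    cfg = ElasticNetConfig(alpha=0.5, n_lambdas=30, lambda_min_ratio=0.05,
                           convergence_tol=1e-8)
    path = weighted_coxnet_path(X, (None, stop, event), w, cfg)

    assert path["lambda_max"] == pytest.approx(0.2958815221412523, rel=1e-6)
    reference = {
        0: np.zeros(10),
        10: np.array([0.20042936, -0.24984757, 0.19818899, 0.06752705,
                      0., 0., 0., 0., 0., 0.]),
        20: np.array([0.30235469, -0.37892807, 0.3088492, 0.12456242,
                      0., -0.01673124, 0., 0., 0., 0.0175776]),
        29: np.array([0.34079708, -0.42976735, 0.35328414, 0.14929831,
                      0., -0.04457426, 0., 0., 0., 0.049174]),
    }
    for j, expect in reference.items():
        assert np.abs(path["coefs"][:, j] - expect).max() < 5e-5


def test_kkt_conditions_along_path(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    cfg = ElasticNetConfig(alpha=0.5, n_lambdas=40, convergence_tol=1e-8)
    path = weighted_coxnet_path(X, (entry, stop, event), w, cfg,
                                return_standardized=True)
    v = w / w.sum()
    Xs, _, _ = _standardize(X, v, True)
    worst = max(
        kkt_violation(Xs, entry, stop, event, v, path["coefs_std"][:, k],
                      lam, 0.5)
        for k, lam in enumerate(path["lambdas"])
    )
    assert worst < 1e-6


def test_objective_monotone_and_path_continuous(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    cfg = ElasticNetConfig(alpha=0.5, n_lambdas=100)
    path = weighted_coxnet_path(X, (entry, stop, event), w, cfg)
    for objs in path["objective_paths"]:
        assert np.all(np.diff(objs) <= 1e-10)
    steps = np.abs(np.diff(path["coefs"], axis=1)).max(axis=0)
    assert steps.max() < 0.25  # smooth along a 100-point path


def test_scale_equivariance_at_lambda_zero(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    m1 = CoxnetRiskScore(cv=0, lambda_fixed=0.0, tol=1e-9).fit(
        X, (event, stop), sample_weight=w, entry=entry)
    X2 = X.copy()
    X2[:, 0] *= 7.0
    m2 = CoxnetRiskScore(cv=0, lambda_fixed=0.0, tol=1e-9).fit(
        X2, (event, stop), sample_weight=w, entry=entry)
    assert m2.coef_[0] == pytest.approx(m1.coef_[0] / 7.0, rel=1e-5)
    assert np.allclose(m2.coef_[1:], m1.coef_[1:], rtol=1e-5, atol=1e-8)


def test_cv_pure_noise_selects_nothing():
    """Null features: the CV-selected model is empty in >= 90% of runs."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n, p = 200, 20
        X = rng.normal(size=(n, p))
        stop = rng.exponential(1.0, n)
        event = rng.random(n) < 0.6
        m = CoxnetRiskScore(alpha=0.5, cv=5, random_state=seed).fit(
            X, (event.astype(int), stop))
        hits += int(m.selected_.sum() == 0)
    assert hits >= 9


def test_cv_overwhelming_feature_always_selected():
    """One feature at HR 3 per SD is selected at the chosen lambda."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        n, p = 500, 10
        X = rng.normal(size=(n, p))
        T = rng.exponential(1 / (0.2 * np.exp(np.log(3.0) * X[:, 0])))
        C = rng.exponential(5.0, n)
        stop = np.minimum(T, C)
        event = (T <= C).astype(int)
        m = CoxnetRiskScore(alpha=0.5, cv=5, random_state=seed).fit(
            X, (event, stop))
        hits += int(m.selected_[0])
    assert hits >= 10 * 0.95


def test_cv_deterministic_under_seed(survival_fixture):
    X, entry, stop, event, w = survival_fixture
    kw = dict(sample_weight=w, entry=entry)
    m1 = CoxnetRiskScore(cv=4, random_state=3).fit(X, (event, stop), **kw)
    m2 = CoxnetRiskScore(cv=4, random_state=3).fit(X, (event, stop), **kw)
    assert m1.lambda_ == m2.lambda_
    assert np.array_equal(m1.coef_, m2.coef_)
    pd.testing.assert_frame_equal(m1.cv_curve_, m2.cv_curve_)


@pytest.mark.parametrize("bad", ["no_events", "rising_path", "neg_weights"])
def test_input_validation(survival_fixture, bad):
    X, entry, stop, event, w = survival_fixture
    if bad == "no_events":
        with pytest.raises(ValueError, match="events"):
            weighted_coxnet_path(X, (entry, stop, np.zeros_like(event)), w)
    elif bad == "rising_path":
        with pytest.raises(ValueError, match="decreasing"):
            ElasticNetConfig(lambda_path=[0.1, 0.2])
    else:
        with pytest.raises(ValueError, match="weights"):
            weighted_coxnet_path(X, (entry, stop, event), -w)
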