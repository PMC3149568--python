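"""Solver, RLS refit, prediction and confusion decomposition."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from l1l2sig import (DoubleOptimizationClassifier, ElasticNetSelector,
                     RLSClassifier, confusion, enet_objective,
                     fit_elastic_net, fit_rls, kkt_residuals, predict_labels,
                     soft_threshold, tau_max)
from l1l2sig.exact import enet_bruteforce
from l1l2sig.linear_model import rls_path


@pytest.mark.parametrize("v, gamma, expected", [
    (1.2, 0.5, 0.7),
    (-0.3, 1.0, 0.0),
    (-2.0, 0.5, -1.5),
])
def test_soft_threshold_definition(v, gamma, expected):
    assert soft_threshold(np.array([v]), gamma)[0] == pytest.approx(expected)


def test_soft_threshold_zero_gamma_is_identity(rng):
    v = rng.standard_normal(20)
    np.testing.assert_array_equal(soft_threshold(v, 0.0), v)


def test_soft_threshold_rejects_negative_gamma():
    with pytest.raises(ValueError, match="soft-threshold"):
        soft_threshold(np.ones(3), -0.1)


def _orthonormal_design(rng, n=16, d=5):
    Q, _ = np.linalg.qr(rng.standard_normal((n, d)))
    return np.sqrt(n) * Q  # X'X = n I


@pytest.mark.parametrize("tau", [0.2, 0.7, 1.3])
@pytest.mark.parametrize("mu", [0.0, 0.5, 1.0])
def test_orthonormal_design_closed_form(rng, tau, mu):
    """On an orthonormal design the minimizer decouples per coordinate:
    beta_j = soft_threshold(yhat_j, tau/2) / (1 + mu)."""
    X = _orthonormal_design(rng)
    y = rng.standard_normal(X.shape[0])
    n = X.shape[0]
    yhat = X.T @ y / n
    expected = soft_threshold(yhat, tau / 2.0) / (1.0 + mu)
    beta, _, ok = fit_elastic_net(X, y, tau, mu, tol=1e-12, max_iter=200_000)
    assert ok
    np.testing.assert_allclose(beta, expected, atol=1e-8)


def test_zero_solution_above_tau_max(rng):
    X = rng.standard_normal((15, 8))
    X -= X.mean(axis=0)
    y = np.sign(rng.standard_normal(15))
    t_max = tau_max(X, y)
    beta, _, _ = fit_elastic_net(X, y, t_max * 1.001, mu=0.3, tol=1e-10)
    assert np.all(beta == 0)


@pytest.mark.parametrize("mu", [0.1, 1.0])
def test_duplicated_columns_get_equal_weights(rng, mu):
    """The strict convexity added by the l2 term forces exactly duplicated
    variables to share their weight (the grouping effect)."""
    X = rng.standard_normal((25, 6))
    X[:, 3] = X[:, 0]
    X -= X.mean(axis=0)
    y = np.sign(X[:, 0] + 0.3 * rng.standard_normal(25))
    beta, _, ok = fit_elastic_net(X, y, tau=0.05, mu=mu, tol=1e-12,
                                  max_iter=500_000)
    assert ok
    assert beta[0] != 0
    assert abs(beta[0] - beta[3]) < 1e-8
    # swap-columns oracle: permuting the duplicated pair changes nothing
    Xs = X.copy()
    Xs[:, [0, 3]] = Xs[:, [3, 0]]
    beta_s, _, _ = fit_elastic_net(Xs, y, tau=0.05, mu=mu, tol=1e-12,
                                   max_iter=500_000)
    np.testing.assert_allclose(beta, beta_s, atol=1e-8)


def test_monotone_descent_of_ista_iterates(rng):
    """Truncating ISTA at k iterations gives the k-th iterate (the solver is
    deterministic from the zero start), so objectives must be
    non-increasing in k."""
    X = rng.standard_normal((20, 10))
    X -= X.mean(axis=0)
    y = np.sign(rng.standard_normal(20))
    objs = []
    for k in range(1, 40):
        beta, _, _ = fit_elastic_net(X, y, tau=0.1, mu=0.5, tol=0.0,
                                     max_iter=k, warn=False)
        objs.append(enet_objective(X, y, beta, 0.1, 0.5))
    assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))


def test_kkt_conditions_hold_at_solution(rng):
    for _ in range(5):
        X = rng.standard_normal((12, 6))
        X -= X.mean(axis=0)
        y = np.sign(rng.standard_normal(12))
        tau, mu = 0.15, 0.4
        beta, _, ok = fit_elastic_net(X, y, tau, mu, tol=1e-9,
                                      max_iter=500_000)
        assert ok
        assert kkt_residuals(X, y, beta, tau, mu).max() < 1e-6


def test_solver_matches_enumeration_oracle(rng):
    """ISTA objective agrees with the sign-pattern enumeration optimum."""
    for _ in range(8):
        n, d = rng.integers(4, 11), rng.integers(2, 7)
        X = rng.standard_normal((n, d))
        X -= X.mean(axis=0)
        y = np.sign(rng.standard_normal(n))
        tau = float(rng.uniform(0.05, 0.5))
        mu = float(rng.uniform(0.0, 1.0))
        beta, _, _ = fit_elastic_net(X, y, tau, mu, tol=1e-10,
                                     max_iter=500_000)
        _, obj_star = enet_bruteforce(X, y, tau, mu)
        assert enet_objective(X, y, beta, tau, mu) <= obj_star + 1e-6


def test_nonfinite_input_rejected():
    X = np.ones((4, 2))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_elastic_net(X, np.ones(4), tau=0.1, mu=0.1)


def test_rls_one_dimensional_closed_form():
    X = np.array([[1.0], [-1.0]])
    y = np.array([1.0, -1.0])
    beta = fit_rls(X, y, lam=1.0)  # (X'X + n lam)^-1 X'y = 2 / (2 + 2)
    assert beta[0] == pytest.approx(0.5)


def test_rls_zero_lambda_is_ols(rng):
    X = rng.standard_normal((20, 4))
    y = rng.standard_normal(20)
    np.testing.assert_allclose(fit_rls(X, y, 0.0),
                               np.linalg.lstsq(X, y, rcond=None)[0],
                               atol=1e-10)


def test_rls_shrinks_monotonically(rng):
    X = rng.standard_normal((15, 5))
    y = rng.standard_normal(15)
    norms = [np.linalg.norm(fit_rls(X, y, lam))
             for lam in (0.0, 0.1, 1.0, 10.0, 1e4)]
    assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-2 * norms[0]


def test_rls_empty_support_is_an_error():
    with pytest.raises(ValueError, match="empty selection"):
        fit_rls(np.empty((4, 0)), np.ones(4), 0.1)


def test_rls_path_matches_single_fits_both_branches(rng):
    lams = [1e-3, 0.1, 1.0]
    for n, s in [(20, 6), (6, 20)]:  # primal and dual (kernel) branches
        X = rng.standard_normal((n, s))
        y = rng.standard_normal(n)
        B = rls_path(X, y, lams)
        for b, lam in zip(B, lams):
            np.testing.assert_allclose(b, fit_rls(X, y, lam), atol=1e-8)


@pytest.mark.parametrize("x, expected", [
    ((2.0, 7.3), 1.0),
    ((-0.5, 9.0), -1.0),
    ((0.0, 4.0), 1.0),  # tie at exactly zero goes to the positive class
])
def test_predict_sign_rule(x, expected):
    beta = np.array([1.0, 0.0])
    assert predict_labels(beta, np.array([x]))[0] == expected


def test_prediction_invariant_to_constant_column_shift(rng):
    """Adding a constant to a variable in both train and test is absorbed
    by the training-mean centering and cannot change predictions."""
    X = rng.standard_normal((40, 10))
    y = np.sign(X[:, 0] + 0.2 * rng.standard_normal(40))
    Xt = rng.standard_normal((15, 10))
    clf = DoubleOptimizationClassifier(tau=0.05, mu=1.0, lam=0.01).fit(X, y)
    pred = clf.predict(Xt)
    shift = np.zeros(10)
    shift[0] = 57.0
    clf2 = DoubleOptimizationClassifier(tau=0.05, mu=1.0, lam=0.01).fit(
        X + shift, y)
    np.testing.assert_array_equal(clf2.predict(Xt + shift), pred)


def test_confusion_counts_and_error():
    truth = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1], dtype=float)
    c = confusion(truth, truth)
    assert (c.TP, c.TN, c.FP, c.FN) == (5, 5, 0, 0) and c.error == 0
    c = confusion(-truth, truth)
    assert (c.TP, c.TN) == (0, 0) and c.error == 1
    c = confusion(np.array([1.0, 1, -1, 1]), np.array([1.0, 1, -1, -1]))
    assert c.FP == 1 and c.error == pytest.approx(0.25)


def test_confusion_rejects_bad_labels():
    with pytest.raises(ValueError, match="labels"):
        confusion(np.array([1.0, 0.0]), np.array([1.0, -1.0]))
    with pytest.raises(ValueError, match="mismatch"):
        confusion(np.array([1.0]), np.array([1.0, -1.0]))


def test_estimators_are_sklearn_compatible(rng):
    X = rng.standard_normal((30, 12))
    y = np.sign(X[:, 0] + 0.1 * rng.standard_normal(30))
    sel = ElasticNetSelector(tau=0.1, mu=1.0)
    assert clone(sel).get_params()["tau"] == 0.1
    sel.fit(X, y)
    assert sel.transform(X).shape[1] == sel.support_.sum() > 0
    pipe = Pipeline([("select", ElasticNetSelector(tau=0.1, mu=1.0)),
                     ("classify", RLSClassifier(lam=0.01))])
    pipe.fit(X, y)
    assert set(np.unique(pipe.predict(X))) <= {-1.0, 1.0}
    assert 1 - np.mean(pipe.predict(X) == y) < 0.2


def test_empty_selection_falls_back_to_majority(rng):
    X = rng.standard_normal((20, 5))
    y = np.array([1.0] * 12 + [-1.0] * 8)
    clf = DoubleOptimizationClassifier(tau=1e6, mu=1.0).fit(X, y)
    assert clf.fallback_label_ == 1.0
    assert np.all(clf.predict(rng.standard_normal((7, 5))) == 1.0)
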