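"""Sparse linear models for two-class signature discovery.

The selection/classification engine is a *double optimization*: a naive
elastic-net fit solved by iterative soft-thresholding (ISTA) picks a sparse,
correlation-aware support, and a regularized least-squares (RLS / ridge) refit
on that support produces the classifier whose sign assigns class labels.

Objective conventions
---------------------
Elastic net:   (1/n) ||y - X b||_2^2 + tau ||b||_1 + mu ||b||_2^2
RLS:           (1/n) ||y - X b||_2^2 + lam ||b||_2^2

Labels are -1/+1 and the intercept is identically zero: matrices are centered
column-wise before fitting, so the offset is absorbed by the centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "soft_threshold",
    "enet_objective",
    "kkt_residuals",
    "fit_elastic_net",
    "enet_path",
    "tau_max",
    "fit_rls",
    "rls_path",
    "predict_labels",
    "WeightVector",
    "ConfusionCounts",
    "confusion",
    "ElasticNetSelector",
    "RLSClassifier",
    "DoubleOptimizationClassifier",
]


class ConvergenceWarning(UserWarning):
    """ISTA stopped at ``max_iter`` before reaching the requested tolerance."""


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError(f"X must be 2-dimensional, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite entries")
    return X, y


def _check_labels(y):
    y = np.asarray(y).ravel()
    bad = set(np.unique(y)) - {-1, 1, -1.0, 1.0}
    if bad:
        raise ValueError(f"labels must be -1/+1, found {sorted(bad)}")
    return y.astype(float)


def soft_threshold(v, gamma):
    """Elementwise soft-thresholding ``sign(v) * max(|v| - gamma, 0)``.

    This is the proximal operator of ``gamma * ||.||_1`` and the single
    nonlinearity of the ISTA iteration.
    """
    if gamma < 0:
        raise ValueError(f"soft-threshold parameter must be >= 0, got {gamma}")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - gamma, 0.0)


def enet_objective(X, y, beta, tau, mu):
    """Value of the naive elastic-net functional at ``beta``."""
    n = X.shape[0]
    r = y - X @ beta
    return (r @ r) / n + tau * np.abs(beta).sum() + mu * (beta @ beta)


def kkt_residuals(X, y, beta, tau, mu):
    """Per-coordinate violation of the elastic-net optimality conditions.

    For active coordinates the stationarity residual
    ``|(2/n) X_j'(Xb - y) + 2 mu b_j + tau sign(b_j)|`` is returned; for
    inactive ones the amount by which ``|(2/n) X_j'(y - Xb)|`` exceeds
    ``tau`` (zero when inside the subgradient interval).
    """
    n = X.shape[0]
    grad = (2.0 / n) * (X.T @ (X @ beta - y)) + 2.0 * mu * beta
    active = beta != 0
    res = np.empty_like(beta)
    res[active] = np.abs(grad[active] + tau * np.sign(beta[active]))
    res[~active] = np.maximum(np.abs(grad[~active]) - tau, 0.0)
    return res


def tau_max(X, y):
    """Smallest l1 weight for which the all-zero vector is optimal.

    Equals ``max_j |(2/n) X_j' y|`` under the adopted ``1/n`` scaling.
    """
    n = X.shape[0]
    return np.max(np.abs((2.0 / n) * (X.T @ y)))


def _step_constant(X, mu, n):
    # C >= Lipschitz constant 2(sigma_max(X'X)/n + mu) guarantees descent.
    smax = np.linalg.norm(X, 2)
    return 2.0 * (smax * smax / n + mu)


def _ista(X, y, tau, mu, C, beta, tol, max_iter, Xty):
    n = X.shape[0]
    two_n = 2.0 / n
    thr = tau / C
    for it in range(max_iter):
        grad = two_n * (X.T @ (X @ beta) - Xty) + 2.0 * mu * beta
        v = beta - grad / C
        beta_new = np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)
        delta = np.max(np.abs(beta_new - beta)) if beta.size else 0.0
        beta = beta_new
        if delta < tol:
            return beta, it + 1, True
    return beta, max_iter, False


def fit_elastic_net(X, y, tau, mu, tol=1e-6, max_iter=100_000, beta0=None,
                    warn=True):
    """Minimize the naive elastic-net functional by ISTA.

    Parameters
    ----------
    X : (n, d) centered design matrix.
    y : (n,) -1/+1 labels (treated as real responses).
    tau : positive l1 penalty weight (sparsity).
    mu : nonnegative l2 penalty weight (correlation preservation).
    tol : stopping tolerance on the max-norm coefficient change.
    max_iter : iteration cap; hitting it flags non-convergence.
    beta0 : optional warm start.

    Returns
    -------
    beta : (d,) coefficient vector.
    n_iter : iterations run.
    converged : whether ``tol`` was reached.
    """
    X, y = _check_Xy(X, y)
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    n, d = X.shape
    beta = np.zeros(d) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    C = _step_constant(X, mu, n)
    beta, n_iter, converged = _ista(X, y, tau, mu, C, beta, tol, max_iter,
                                    X.T @ y)
    if not converged and warn:
        warnings.warn(
            f"ISTA did not reach tol={tol} within {max_iter} iterations",
            ConvergenceWarning,
        )
    return beta, n_iter, converged


def enet_path(X, y, taus, mu, tol=1e-6, max_iter=100_000, warn=True):
    """Elastic-net solutions along a decreasing ``tau`` path with warm starts.

    Returns an array of shape ``(len(taus), d)``; row ``i`` solves the
    functional at ``taus[i]``. Warm-starting each fit from the previous
    (sparser) solution makes grid evaluation in cross-validation cheap.
    """
    X, y = _check_Xy(X, y)
    taus = np.asarray(taus, dtype=float)
    if np.any(np.diff(taus) > 0):
        raise ValueError("taus must be non-increasing for warm starts")
    n, d = X.shape
    C = _step_constant(X, mu, n)
    Xty = X.T @ y
    betas = np.zeros((len(taus), d))
    beta = np.zeros(d)
    all_ok = True
    for i, tau in enumerate(taus):
        beta, _, ok = _ista(X, y, tau, mu, C, beta.copy(), tol, max_iter, Xty)
        betas[i] = beta
        all_ok &= ok
    if not all_ok and warn:
        warnings.warn(
            f"ISTA path did not fully converge at tol={tol}", ConvergenceWarning
        )
    return betas


def fit_rls(X, y, lam):
    """Regularized least squares ``(X'X + n lam I)^-1 X'y`` on a support.

    Uses the dual (kernel) formulation when the sample count is smaller than
    the number of retained variables, which is the common case after a sparse
    selection on wide omics matrices.
    """
    X, y = _check_Xy(X, y)
    if X.shape[1] == 0:
        raise ValueError("empty selection: RLS requires a nonempty support")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    n, s = X.shape
    if s <= n:
        G = X.T @ X + n * lam * np.eye(s)
        return np.linalg.solve(G, X.T @ y)
    K = X @ X.T + n * lam * np.eye(n)
    return X.T @ np.linalg.solve(K, y)


def rls_path(X, y, lams):
    """RLS solutions for several ridge parameters via one eigendecomposition.

    Factorizes the smaller Gram matrix once, then each ``lam`` costs a
    diagonal solve. Returns an array ``(len(lams), s)``.
    """
    X, y = _check_Xy(X, y)
    if X.shape[1] == 0:
        raise ValueError("empty selection: RLS requires a nonempty support")
    n, s = X.shape
    lams = np.asarray(lams, dtype=float)
    if s <= n:
        w, V = np.linalg.eigh(X.T @ X)
        b = V.T @ (X.T @ y)
        return np.stack([V @ (b / (w + n * lam)) for lam in lams])
    w, V = np.linalg.eigh(X @ X.T)
    b = V.T @ y
    return np.stack([X.T @ (V @ (b / (w + n * lam))) for lam in lams])


def predict_labels(beta, X_new, column_means=None):
    """Classify rows of ``X_new`` by the sign of the linear score.

    ``column_means`` must be the *training* centering vector; a zero score is
    assigned to the positive class (documented tie-break).
    """
    X_new = np.asarray(X_new, dtype=float)
    if column_means is not None:
        X_new = X_new - np.asarray(column_means, dtype=float)
    score = X_new @ np.asarray(beta, dtype=float)
    pred = np.where(score >= 0, 1.0, -1.0)
    return pred


@dataclass
class WeightVector:
    """A fitted sparse linear model ``f(x) = x . beta`` (zero offset)."""

    beta: np.ndarray
    tau: float | None = None
    mu: float | None = None
    lam: float | None = None
    variable_ids: list[str] | None = None
    converged: bool = True

    @property
    def support(self):
        """Indices of nonzero coefficients."""
        return np.flatnonzero(self.beta)

    @property
    def support_ids(self):
        if self.variable_ids is None:
            raise ValueError("no variable_ids attached to this model")
        return [self.variable_ids[j] for j in self.support]


@dataclass
class ConfusionCounts:
    """2x2 confusion decomposition with +1 = diseased as positive class."""

    TP: int
    FN: int
    FP: int
    TN: int

    @property
    def total(self):
        return self.TP + self.FN + self.FP + self.TN

    @property
    def error(self):
        return (self.FP + self.FN) / self.total

    def as_dict(self):
        return {"TP": self.TP, "FN": self.FN, "FP": self.FP, "TN": self.TN,
                "error": self.error}


def confusion(pred, truth):
    """TP/FN/FP/TN counts of a -1/+1 prediction against -1/+1 truth."""
    pred = _check_labels(pred)
    truth = _check_labels(truth)
    if pred.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions, "
            f"{truth.shape[0]} truths"
        )
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (truth == 1))),
        FN=int(np.sum((pred == -1) & (truth == 1))),
        FP=int(np.sum((pred == 1) & (truth == -1))),
        TN=int(np.sum((pred == -1) & (truth == -1))),
    )


class _CenteredModelMixin:
    def _center_fit(self, X):
        self.column_means_ = X.mean(axis=0)
        return X - self.column_means_

    def _center_apply(self, X):
        return np.asarray(X, dtype=float) - self.column_means_


class ElasticNetSelector(SelectorMixin, BaseEstimator, _CenteredModelMixin):
    """Feature selection by the l1l2 (naive elastic-net) functional.

    scikit-learn compatible selector: ``fit(X, y)`` centers the columns,
    runs ISTA and exposes the nonzero-coefficient mask through
    ``get_support`` / ``transform``.

    Parameters
    ----------
    tau : float
        l1 penalty weight; larger values select fewer variables.
    mu : float, default 1.0
        l2 penalty weight; larger values let groups of correlated variables
        enter the selection together.
    tol, max_iter : ISTA stopping rule.

    Attributes
    ----------
    coef_ : (d,) fitted coefficients (zeros off-support).
    support_ : (d,) boolean selection mask.
    n_iter_, converged_ : solver diagnostics.
    column_means_ : training centering vector.
    """

    def __init__(self, tau=0.1, mu=1.0, tol=1e-6, max_iter=100_000):
        self.tau = tau
        self.mu = mu
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        y = _check_labels(y)
        Xc = self._center_fit(X)
        beta, n_iter, converged = fit_elastic_net(
            Xc, y, self.tau, self.mu, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_ = beta
        self.support_ = beta != 0
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


class RLSClassifier(ClassifierMixin, BaseEstimator, _CenteredModelMixin):
    """Regularized least-squares (ridge) classifier on -1/+1 labels.

    The decision rule is ``sign(x . beta)`` with the matrix centered by the
    training column means; ties at exactly zero go to the positive class.
    """

    def __init__(self, lam=1e-3):
        self.lam = lam

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        y = _check_labels(y)
        Xc = self._center_fit(X)
        self.coef_ = fit_rls(Xc, y, self.lam)
        self.classes_ = np.array([-1.0, 1.0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        return self._center_apply(X) @ self.coef_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, 1.0, -1.0)


class DoubleOptimizationClassifier(ClassifierMixin, BaseEstimator,
                                   _CenteredModelMixin):
    """Elastic-net selection followed by an RLS refit on the support.

    This is the two-stage l1l2 estimator: ISTA at ``(tau, mu)`` determines
    which variables carry the signature, then ridge at ``lam`` re-estimates
    their weights for classification. If the selection is empty the fitted
    model falls back to the majority class of the training labels.

    Attributes
    ----------
    coef_ : (d,) full-length coefficients, zeros off the selected support.
    support_ : boolean selection mask.
    fallback_label_ : majority label used when the selection is empty, else None.
    """

    def __init__(self, tau=0.1, mu=1.0, lam=1e-3, tol=1e-6, max_iter=100_000):
        self.tau = tau
        self.mu = mu
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        y = _check_labels(y)
        Xc = self._center_fit(X)
        beta, _, converged = fit_elastic_net(
            Xc, y, self.tau, self.mu, tol=self.tol, max_iter=self.max_iter
        )
        self.support_ = beta != 0
        self.converged_ = converged
        self.coef_ = np.zeros(X.shape[1])
        if self.support_.any():
            self.coef_[self.support_] = fit_rls(Xc[:, self.support_], y,
                                                self.lam)
            self.fallback_label_ = None
        else:
            # empty selection: predict the majority training class
            self.fallback_label_ = 1.0 if np.sum(y == 1) >= np.sum(y == -1) else -1.0
        self.classes_ = np.array([-1.0, 1.0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        if self.fallback_label_ is not None:
            return np.full(np.asarray(X).shape[0], self.fallback_label_)
        return self._center_apply(X) @ self.coef_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, 1.0, -1.0)
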