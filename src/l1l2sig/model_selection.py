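"""Nested stratified K-fold cross-validation for the l1l2 framework.

The inner loop grid-searches the regularization pair (tau*, lambda*) of the
double optimization; the outer loop estimates prediction error and yields
one selected-variable list per fold. The per-variable *frequency score* —
the percentage of outer lists containing a variable — is the stability
criterion used downstream to extract a signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset
from .linear_model import (ConfusionCounts, confusion, enet_path, fit_rls,
                           rls_path, tau_max)

__all__ = ["FoldPlan", "RegularizationGrid", "CVResult",
           "stratified_kfold", "inner_select", "nested_cv"]


@dataclass
class FoldPlan:
    """A stratified partition of samples into K folds."""

    K: int
    assignments: np.ndarray  # sample index -> fold index
    seed: int

    def split(self):
        """Yield ``(train_idx, test_idx)`` pairs, one per fold."""
        for k in range(self.K):
            test = np.flatnonzero(self.assignments == k)
            train = np.flatnonzero(self.assignments != k)
            yield train, test


def stratified_kfold(labels, K, seed):
    """Stratified K-fold plan on -1/+1 labels, deterministic given seed.

    Folds are roughly equal-sized with per-class counts across folds
    differing by at most one, so the class proportions (equivalently the
    mean response) are approximately equal in every fold.
    """
    labels = np.asarray(labels, dtype=float).ravel()
    if not np.all(np.abs(labels) == 1):
        bad = sorted(set(labels) - {-1.0, 1.0})
        raise ValueError(f"labels must be -1/+1, found {bad}")
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    for cls in (-1.0, 1.0):
        count = int(np.sum(labels == cls))
        if count < K:
            raise ValueError(
                f"class {cls:+.0f} has only {count} samples, fewer than "
                f"K={K} folds")
    skf = StratifiedKFold(n_splits=K, shuffle=True,
                          random_state=int(seed) % (2**32))
    assignments = np.empty(labels.shape[0], dtype=int)
    for k, (_, test) in enumerate(skf.split(np.zeros_like(labels), labels)):
        assignments[test] = k
    return FoldPlan(K=K, assignments=assignments, seed=int(seed))


@dataclass
class RegularizationGrid:
    """The (tau, lambda) search grid of the double optimization.

    ``tau_values`` may be left ``None``, in which case each training part
    gets 20 log-spaced values in ``[tau_max/1000, tau_max]`` with
    ``tau_max = max_j |(2/n) X_j' y|`` computed on that part (the smallest
    tau whose solution is all-zero). ``lambda_values`` default to 7
    log-spaced values in ``[1e-4, 10]``.
    """

    tau_values: np.ndarray | None = None
    lambda_values: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 1, 7))
    n_tau: int = 20
    tau_min_ratio: float = 1e-3

    def __post_init__(self):
        if self.tau_values is not None:
            self.tau_values = np.asarray(self.tau_values, dtype=float)
            if self.tau_values.size == 0:
                raise ValueError("tau_values must be nonempty")
            if np.any(np.diff(self.tau_values) > 0):
                raise ValueError("tau_values must be decreasing")
            if np.any(self.tau_values <= 0):
                raise ValueError("tau_values must be positive")
        self.lambda_values = np.asarray(self.lambda_values, dtype=float)
        if self.lambda_values.size == 0:
            raise ValueError("lambda_values must be nonempty")
        if np.any(self.lambda_values < 0):
            raise ValueError("lambda_values must be nonnegative")

    def taus_for(self, X, y):
        """Concrete decreasing tau grid for a training part."""
        if self.tau_values is not None:
            return self.tau_values
        t_max = tau_max(X, y)
        if t_max == 0:
            raise ValueError("degenerate training part: X'y is identically 0")
        return np.logspace(np.log10(t_max),
                           np.log10(t_max * self.tau_min_ratio), self.n_tau)


@dataclass
class CVResult:
    """Outcome of one nested cross-validation run at a fixed mu."""

    mu: float
    K: int
    seed: int
    variable_ids: list
    fold_selected: list          # per outer fold: list of variable ids
    fold_params: list            # per outer fold: (tau_star, lambda_star)
    fold_confusion: list         # per outer fold: ConfusionCounts
    frequencies: pd.Series       # variable id -> % of outer lists containing it

    @property
    def fold_errors(self):
        return [c.error for c in self.fold_confusion]

    @property
    def mean_error(self):
        return float(np.mean(self.fold_errors))


def _majority_error(y_train, y_val):
    maj = 1.0 if np.sum(y_train == 1) >= np.sum(y_train == -1) else -1.0
    return float(np.mean(y_val != maj))


def inner_select(X, y, grid, mu, K_inner, seed, tol=1e-5, max_iter=10_000):
    """Choose (tau*, lambda*) by K-fold CV of the select-then-RLS composite.

    Every inner training part is centered on itself and its validation part
    centered with the training means. Cells whose elastic-net selection is
    empty on some fold are scored with that fold's majority-class error
    rather than dropped, which keeps the comparison defined without favoring
    dense models. Ties are broken toward larger tau (sparser model), then
    smaller lambda.

    Returns ``(tau_star, lambda_star, mean_error_at_optimum)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    taus = grid.taus_for(X - X.mean(axis=0), y)
    lams = grid.lambda_values
    errors = np.zeros((taus.size, lams.size))
    plan = stratified_kfold(y, K_inner, seed)
    for train, val in plan.split():
        Xtr, ytr = X[train], y[train]
        means = Xtr.mean(axis=0)
        Xtr = Xtr - means
        Xval = X[val] - means
        yval = y[val]
        betas = enet_path(Xtr, ytr, taus, mu, tol=tol, max_iter=max_iter,
                          warn=False)
        maj_err = _majority_error(ytr, yval)
        for i in range(taus.size):
            support = betas[i] != 0
            if not support.any():
                errors[i, :] += maj_err
                continue
            B = rls_path(Xtr[:, support], ytr, lams)  # (n_lam, s)
            scores = Xval[:, support] @ B.T           # (n_val, n_lam)
            preds = np.where(scores >= 0, 1.0, -1.0)
            errors[i, :] += np.mean(preds != yval[:, None], axis=0)
    errors /= plan.K
    # lexicographic tie-break: min error, then larger tau, then smaller lambda
    best = None
    for i in range(taus.size):
        for j in range(lams.size):
            key = (errors[i, j], i, j)  # taus are decreasing: smaller i = larger tau
            if best is None or key < best:
                best = key
    _, i, j = best
    return float(taus[i]), float(lams[j]), float(errors[i, j])


def nested_cv(data: LabeledDataset, grid=None, mu=1.0, K_outer=10,
              K_inner=10, seed=0, tol=1e-5, max_iter=10_000):
    """Nested stratified cross-validation of the l1l2 double optimization.

    For each outer fold: the inner loop picks ``(tau*, lambda*)`` on the
    outer-training part; the elastic net is refit there at ``(tau*, mu)``
    and RLS at ``lambda*`` on the selected support; the outer test part
    (centered with outer-training means) yields a ConfusionCounts. The
    result carries one selected list per fold and the per-variable
    frequency scores.

    All randomness derives from ``seed`` (fold plans for both loop levels).
    """
    if grid is None:
        grid = RegularizationGrid()
    X, y = data.X, data.y
    ss = np.random.SeedSequence(int(seed))
    outer_seed, *inner_seeds = [int(s) for s in
                                ss.generate_state(K_outer + 1)]
    plan = stratified_kfold(y, K_outer, outer_seed)
    fold_selected, fold_params, fold_conf = [], [], []
    for k, (train, test) in enumerate(plan.split()):
        try:
            Xtr, ytr = X[train], y[train]
            t_star, l_star, _ = inner_select(
                Xtr, ytr, grid, mu, K_inner, inner_seeds[k],
                tol=tol, max_iter=max_iter)
            means = Xtr.mean(axis=0)
            Xc = Xtr - means
            betas = enet_path(Xc, ytr, [t_star], mu, tol=tol,
                              max_iter=max_iter, warn=False)
            support = betas[0] != 0
            Xtest = X[test] - means
            if support.any():
                b = fit_rls(Xc[:, support], ytr, l_star)
                scores = Xtest[:, support] @ b
                pred = np.where(scores >= 0, 1.0, -1.0)
                selected = [data.variable_ids[j]
                            for j in np.flatnonzero(support)]
            else:
                maj = 1.0 if np.sum(ytr == 1) >= np.sum(ytr == -1) else -1.0
                pred = np.full(test.size, maj)
                selected = []
        except ValueError as exc:
            raise ValueError(f"outer fold {k}: {exc}") from exc
        fold_selected.append(selected)
        fold_params.append((t_star, l_star))
        fold_conf.append(confusion(pred, y[test]))
    counts = pd.Series(0.0, index=pd.Index(data.variable_ids, name="variable"))
    for selected in fold_selected:
        counts[selected] += 1
    freqs = counts * (100.0 / K_outer)
    return CVResult(mu=float(mu), K=K_outer, seed=int(seed),
                    variable_ids=list(data.variable_ids),
                    fold_selected=fold_selected, fold_params=fold_params,
                    fold_confusion=fold_conf, frequencies=freqs)
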