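"""Exact small-scale reference computations for validation.

These are deliberately naive, independent re-derivations used to check the
production code paths: the elastic-net minimizer found by enumerating all
sign patterns of the coefficient vector (feasible for d <= ~8), and the
hypergeometric upper tail computed in exact integer arithmetic. They scale
terribly and exist only as ground truth on tiny instances.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

__all__ = ["enet_bruteforce", "hypergeom_tail_exact"]


def enet_bruteforce(X, y, tau, mu, sign_tol=1e-9):
    """Global minimizer of the naive elastic-net functional by enumeration.

    For each of the 3^d sign patterns of beta the stationarity system on
    the support is solved in closed form and the Karush-Kuhn-Tucker
    conditions verified; among all consistent candidates the lowest
    objective wins. With mu > 0 the functional is strictly convex and the
    consistent candidate is unique up to numerics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if d > 8:
        raise ValueError(f"enumeration over 3^{d} patterns is not sensible")

    def objective(b):
        r = y - X @ b
        return (r @ r) / n + tau * np.abs(b).sum() + mu * (b @ b)

    best = None
    for signs in itertools.product((-1.0, 0.0, 1.0), repeat=d):
        s = np.array(signs)
        S = np.flatnonzero(s)
        b = np.zeros(d)
        if S.size:
            Xs = X[:, S]
            A = (2.0 / n) * (Xs.T @ Xs) + 2.0 * mu * np.eye(S.size)
            c = (2.0 / n) * (Xs.T @ y) - tau * s[S]
            try:
                bS = np.linalg.solve(A, c)
            except np.linalg.LinAlgError:
                bS, *_ = np.linalg.lstsq(A, c, rcond=None)
                if not np.allclose(A @ bS, c, atol=1e-8):
                    continue
            if np.any(bS * s[S] <= sign_tol):
                continue
            b[S] = bS
        # zero coordinates must satisfy the subgradient condition
        r = y - X @ b
        grad0 = (2.0 / n) * (X.T @ r)
        inactive = s == 0
        if np.any(np.abs(grad0[inactive]) > tau * (1 + 1e-9) + 1e-12):
            continue
        obj = objective(b)
        if best is None or obj < best[0]:
            best = (obj, b)
    if best is None:
        raise RuntimeError("no sign pattern satisfied the optimality "
                           "conditions (numerical degeneracy)")
    return best[1], best[0]


def hypergeom_tail_exact(N, K, n, k):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact integer arithmetic."""
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N or k > min(K, n) or min(N, K, n, k) < 0:
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    total = math.comb(N, n)
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(k, min(K, n) + 1)
              if n - i <= N - K)
    return num / total
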