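"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a quantity by a different route than the package:
explicit normal equations for window OLS, a hand-coded Newton/IRLS loop for
logistic maximum likelihood, direct pmf summation for the exact binomial
test, and brute-force support-pair/-triple enumeration for the 2-D
max-margin hyperplane.
"""

from __future__ import annotations

import itertools

import numpy as np


def ols_normal_equations(values) -> tuple[float, float]:
    """Slope and RSS of value ~ index via explicit (X'X)^{-1} X'y."""
    y = np.asarray(values, dtype=float)
    t = np.arange(y.size, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.inv(X.T @ X) @ (X.T @ y)
    resid = y - X @ beta
    return float(beta[1]), float(resid @ resid)


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Newton/IRLS logistic MLE; returns (params, bse, ll)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))
    return beta, np.sqrt(np.diag(cov)), ll


def binom_two_sided_pmf_sum(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p: sum of pmf values <= pmf(k)."""
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(n + 1), n, p)
    return float(np.sum(pmf[pmf <= pmf[k] * (1 + 1e-12)]))


def brute_force_max_margin(points: np.ndarray, labels: np.ndarray):
    """Maximum-margin separating line of 2-D points by support enumeration.

    For linearly separable data the optimal hyperplane is supported either
    by one point of each class (perpendicular bisector of the pair) or by
    two points of one class and one of the other (line parallel to the
    same-class pair).  Enumerates both families, keeps feasible candidates,
    and returns (w, b, margin) of the best.
    """
    pts = np.asarray(points, float)
    lab = np.asarray(labels)
    pos = pts[lab == 1]
    neg = pts[lab == -1]
    best = None

    def consider(w, b):
        nonlocal best
        norm = np.linalg.norm(w)
        if norm == 0:
            return
        dist = (pts @ w + b) / norm
        if np.all(dist * lab > 1e-12):
            margin = np.min(np.abs(dist))
            if best is None or margin > best[2]:
                best = (w / norm, b / norm, margin)

    for p, q in itertools.product(pos, neg):
        w = p - q
        b = -(w @ (p + q)) / 2.0
        consider(w, b)
    for same, other, sign in ((pos, neg, 1), (neg, pos, -1)):
        for a1, a2 in itertools.combinations(same, 2):
            d = a2 - a1
            w = np.array([-d[1], d[0]])
            if w @ np.array([0.0, 0.0]) == w @ a1:  # degenerate direction guard
                pass
            for c in other:
                # plane parallel to (a1, a2), midway between that line and c
                offset_same = w @ a1
                offset_other = w @ c
                if offset_same == offset_other:
                    continue
                b = -(offset_same + offset_other) / 2.0
                wo = w if (offset_same + b) * sign > 0 else -w
                bo = b if (offset_same + b) * sign > 0 else -b
                consider(wo, bo)
    if best is None:
        raise ValueError("points are not linearly separable")
    return best
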