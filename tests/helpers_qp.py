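"""Brute-force dense QP oracle for the soft-margin SVM dual (test-only).

Solves max sum(a) - 1/2 (a*y)' K (a*y) s.t. 0 <= a <= c, a.y = 0 with
multi-start SLSQP; independent of the production working-set solver.
"""

import numpy as np
from scipy.optimize import minimize


def solve_dual_qp(K, y, c, restarts=5, seed=0):
    """Return ``(alpha, dual_objective)`` maximizing the dual."""
    n = len(y)
    rng = np.random.default_rng(seed)

    def obj(a):
        return 0.5 * (a * y) @ K @ (a * y) - a.sum()

    def jac(a):
        return (K @ (a * y)) * y - 1.0

    constraints = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    best = None
    for r in range(restarts):
        x0 = np.zeros(n) if r == 0 else rng.uniform(0, c, n)
        res = minimize(
            obj, x0, jac=jac, bounds=[(0, c)] * n, constraints=constraints,
            method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14},
        )
        if abs(res.x @ y) < 1e-8 and (best is None or res.fun < best.fun):
            best = res
    alpha = np.clip(best.x, 0, c)
    return alpha, -best.fun


def oracle_bias(K, alpha, y, c):
    """Bias from KKT conditions, same convention as the production solver."""
    f = K @ (alpha * y)
    at_lo = alpha <= 1e-8 * c
    at_hi = alpha >= c * (1 - 1e-8)
    free = ~at_lo & ~at_hi
    yf = y - f
    if free.any():
        return float(np.mean(yf[free]))
    pos = y > 0
    up = (pos & ~at_hi) | (~pos & ~at_lo)
    lo = (~pos & ~at_hi) | (pos & ~at_lo)
    hi_v = yf[up].max() if up.any() else 0.0
    lo_v = yf[lo].min() if lo.any() else 0.0
    return float((hi_v + lo_v) / 2)


def random_binary_problem(rng):
    """One random small 2-class problem (points, labels, penalty)."""
    n = int(rng.integers(4, 13))
    d = int(rng.integers(1, 4))
    X = rng.normal(size=(n, d))
    y = np.ones(n)
    y[: n // 2] = -1
    rng.shuffle(y)
    labels = (y < 0).astype(int)
    c = float(rng.uniform(0.5, 3))
    return X, labels, c
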