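"""Independent small-instance oracles used by the tests.

These deliberately avoid the code paths they check: the epsilon-SVR dual is
solved here with a general-purpose SLSQP quadratic program, leverage via an
explicit hat matrix, and OLS via the normal equations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def svr_dual_qp(K: np.ndarray, y: np.ndarray, C: float, epsilon: float,
                tol: float = 1e-12) -> tuple[np.ndarray, float]:
    """Solve the epsilon-SVR dual by SLSQP on 2n box-constrained variables.

    minimize  1/2 b'Kb - y'b + eps * sum(a + a*)   with b = a - a*,
    s.t.      sum(b) = 0,  0 <= a, a* <= C.

    Returns (beta, bias).  The bias comes from the KKT conditions averaged
    over free (strictly inside the box) support vectors.
    """
    n = len(y)

    def objective(z):
        a, astar = z[:n], z[n:]
        b = a - astar
        return 0.5 * b @ K @ b - y @ b + epsilon * np.sum(a + astar)

    def grad(z):
        a, astar = z[:n], z[n:]
        Kb = K @ (a - astar)
        return np.concatenate([Kb - y + epsilon, -(Kb - y) + epsilon])

    cons = [{"type": "eq",
             "fun": lambda z: np.sum(z[:n] - z[n:]),
             "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}]
    bounds = [(0.0, C)] * (2 * n)
    best = None
    for start in (np.zeros(2 * n), np.full(2 * n, min(C, 1.0) / 2)):
        res = minimize(objective, start, jac=grad, bounds=bounds,
                       constraints=cons, method="SLSQP",
                       options={"maxiter": 2000, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
    z = best.x
    a, astar = z[:n], z[n:]
    beta = a - astar
    Kb = K @ beta
    slack = 1e-6 * C
    free_up = (a > slack) & (a < C - slack)
    free_dn = (astar > slack) & (astar < C - slack)
    biases = np.concatenate([
        (y - Kb - epsilon)[free_up],
        (y - Kb + epsilon)[free_dn],
    ])
    if len(biases) == 0:  # every SV at bound: bracket the bias instead
        up = np.where(a >= C - slack, y - Kb - epsilon, -np.inf)
        dn = np.where(astar >= C - slack, y - Kb + epsilon, np.inf)
        lo = np.max(np.concatenate([up, (y - Kb + epsilon)[beta == 0]]))
        hi = np.min(np.concatenate([dn, (y - Kb - epsilon)[beta == 0]]))
        bias = 0.5 * (lo + hi) if np.isfinite(lo) and np.isfinite(hi) else 0.0
    else:
        bias = float(np.mean(biases))
    return beta, bias


def rbf_gram(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-gamma * d2)


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(coefficients incl. intercept, their standard errors) via normal eqs."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = len(y) - A.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    return coef, np.sqrt(np.diag(cov))


def hat_diagonal(X: np.ndarray) -> np.ndarray:
    """Hat-matrix diagonal of the intercept-augmented design (raw scale)."""
    A = np.column_stack([np.ones(len(X)), X])
    H = A @ np.linalg.inv(A.T @ A) @ A.T
    return np.diag(H)
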