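"""Internal weighted logistic regression (Newton-Raphson with step halving).

Used inside the EM M-step, where fractional posterior weights rule out the
usual frequency-weight code paths and a warm-started Newton solve is much
faster than a general-purpose optimizer.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer."""


def loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    check_separation: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Maximize the weighted Bernoulli log-likelihood.

    Returns ``(beta, cov, loglik, converged)`` where ``cov`` is the inverse
    observed information at the optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)

    ll = loglik(beta, X, y, w)
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        grad = X.T @ (w * (y - mu))
        wd = w * mu * (1.0 - mu)
        H = X.T @ (X * wd[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # rank-deficient information: ascend within the identified
            # subspace (the step-halving guard below keeps it monotone)
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # Backtrack if the full Newton step overshoots.
        alpha = 1.0
        while True:
            cand = beta + alpha * step
            ll_new = loglik(cand, X, y, w)
            if ll_new >= ll - 1e-12 or alpha < 1e-10:
                break
            alpha *= 0.5
        delta = float(np.max(np.abs(cand - beta)))
        beta, ll = cand, ll_new
        if delta < tol:
            converged = True
            break
    if check_separation and np.max(np.abs(beta)) > 40.0:
        raise SeparationError("diverging coefficients suggest separation")
    mu = expit(X @ beta)
    wd = w * mu * (1.0 - mu)
    H = X.T @ (X * wd[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, ll, converged
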