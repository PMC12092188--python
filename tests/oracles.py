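"""Independent reference computations used to check the fitted models.

These deliberately avoid statsmodels and the package's own fitting code:
the logistic oracle is a plain Newton-Raphson on the log-likelihood, the
sandwich oracle assembles bread^-1 * meat * bread^-1 explicitly, and the
linear oracle uses Frisch-Waugh-Lovell residual projection.
"""
import numpy as np


def newton_logistic(X, y, tol=1e-12, maxiter=200):
    """Direct likelihood maximization; returns (beta, model covariance)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    b = np.zeros(X.shape[1])
    H = np.eye(X.shape[1])
    for _ in range(maxiter):
        mu = 1.0 / (1.0 + np.exp(-(X @ b)))
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        step = np.linalg.solve(H, X.T @ (y - mu))
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    return b, np.linalg.inv(H)


def hc0_sandwich(X, y, b):
    """Explicit bread^-1 * sum(score_i score_i^T) * bread^-1."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    mu = 1.0 / (1.0 + np.exp(-(X @ b)))
    bread = np.linalg.inv((X * (mu * (1 - mu))[:, None]).T @ X)
    scores = X * (y - mu)[:, None]
    meat = scores.T @ scores
    return bread @ meat @ bread


def fwl_slope(x, y, Z=None):
    """OLS slope of y on x after projecting out [1, Z] from both."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(y)
    Zf = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    rx = x - Zf @ np.linalg.lstsq(Zf, x, rcond=None)[0]
    ry = y - Zf @ np.linalg.lstsq(Zf, y, rcond=None)[0]
    return float(rx @ ry / (rx @ rx))
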