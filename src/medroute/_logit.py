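"""Minimal Newton-Raphson (IRLS) logistic regression.

The mediation bootstrap refits three logistic models per replicate; a bare
numpy IRLS is an order of magnitude faster than a full GLM framework for the
10-column designs used here. Correctness is cross-checked against
statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ConvergenceError

_MAX_ABS_COEF = 40.0  # |beta| beyond this is numerically a separated fit


@dataclass(frozen=True)
class LogitFit:
    coef: np.ndarray
    n_iter: int
    converged: bool
    loglik: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coef)


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
) -> LogitFit:
    """Fit logit P(y=1) = expit(X beta) by Newton-Raphson.

    ``start`` warm-starts the iteration (used by the bootstrap, whose
    resample optima sit close to the full-data fit). Raises ConvergenceError
    on non-convergence or (quasi-)separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * np.maximum(w, 1e-12)[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            raise ConvergenceError(f"non-finite coefficients at iteration {it}")
        if np.max(np.abs(beta)) > _MAX_ABS_COEF:
            raise ConvergenceError(
                "coefficient magnitude exceeded bound; data are likely separated"
            )
        if np.max(np.abs(step)) < tol:
            eta = X @ beta
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            return LogitFit(coef=beta, n_iter=it, converged=True, loglik=ll)
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
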