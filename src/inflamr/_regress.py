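"""Light-weight GLM fitting used in per-SNP association loops.

These are standard IRLS fits (Gaussian identity, binomial logit, Poisson log)
with optional prior weights and HC0 sandwich covariances.  They exist because
the Mendelian-randomisation stage fits thousands of small regressions inside
replicate loops; results are cross-checked against statsmodels in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, special


class SeparationError(RuntimeError):
    """Quasi-complete separation in a binary-response fit."""


@dataclass
class GLMFit:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    family: str
    n: int
    converged: bool

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * special.ndtr(-np.abs(z))


def _solve_wls(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = linalg.lstsq(X * sw[:, None], z * sw, lapack_driver="gelsd")
    return beta


def fit_glm(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "gaussian",
    weights: np.ndarray | None = None,
    robust: bool = False,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GLMFit:
    """Fit a GLM of ``y`` on design matrix ``X`` (must include any intercept).

    family: 'gaussian' (identity), 'binomial' (logit) or 'poisson' (log).
    ``weights`` are prior/IPW weights; ``robust`` requests HC0 sandwich SEs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w0 = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w0 < 0):
        raise ValueError("weights must be non-negative")

    if family == "gaussian":
        beta = _solve_wls(X, y, w0)
        mu = X @ beta
        resid = y - mu
        XtWX = (X * w0[:, None]).T @ X
        A = linalg.pinvh(XtWX)
        if robust:
            score = X * (w0 * resid)[:, None]
            cov = A @ (score.T @ score) @ A
        else:
            dof = max(n - p, 1)
            sigma2 = float(np.sum(w0 * resid**2) / dof)
            cov = sigma2 * A
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return GLMFit(beta, se, cov, family, n, True)

    if family not in ("binomial", "poisson"):
        raise ValueError(f"unknown family {family!r}")

    # IRLS
    if family == "binomial":
        ybar = np.clip(np.average(y, weights=w0), 1e-6, 1 - 1e-6)
        eta = np.full(n, np.log(ybar / (1 - ybar)))
    else:
        eta = np.full(n, np.log(max(np.average(y, weights=w0), 1e-6)))
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        if family == "binomial":
            mu = special.expit(eta)
            var = np.clip(mu * (1 - mu), 1e-12, None)
        else:
            mu = np.exp(np.clip(eta, -500, 30))
            var = np.clip(mu, 1e-12, None)
        z = eta + (y - mu) / var
        w = w0 * var
        beta_new = _solve_wls(X, z, w)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        if step < tol:
            converged = True
            break
    if family == "binomial":
        mu = special.expit(eta)
        var = mu * (1 - mu)
        if not converged and np.max(np.abs(beta)) > 20:
            raise SeparationError(
                "binary-response fit did not converge; coefficients diverging "
                "(possible quasi-complete separation)"
            )
    else:
        mu = np.exp(np.clip(eta, -500, 30))
        var = mu
    XtWX = (X * (w0 * var)[:, None]).T @ X
    A = linalg.pinvh(XtWX)
    if robust:
        score = X * (w0 * (y - mu))[:, None]
        cov = A @ (score.T @ score) @ A
    else:
        cov = A
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return GLMFit(beta, se, cov, family, n, converged)
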