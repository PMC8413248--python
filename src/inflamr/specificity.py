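"""Disorder-specificity testing: is the CRP association depression-specific?

Jointly models probable depression and probable anxiety as a bivariate
probit (latent bivariate-normal errors with correlation rho); a likelihood
ratio test compares the free model against one constraining the CRP
coefficient to be equal across the two equations (covariate coefficients
stay free).  Probit coefficients are converted to odds ratios by the
conventional x1.6 scaling of the probit-to-logit slope.  The continuous
analogue models the two transformed symptom scores as a bivariate Gaussian
system (seemingly unrelated regressions with identical regressors) with the
same equality LRT.  Mutual adjustment (depression on CRP adjusting for
current anxiety symptoms, and vice versa) provides a further specificity
probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from ._bvn import bvn_cdf, bvn_pdf
from .observational import _analysis_frame, _model_design, transform_outcome
from ._regress import fit_glm

_PHI_FLOOR = 1e-300
_GRAD_TOL = 1e-6  # on the mean (per-observation) log-likelihood gradient
_GRAD_FAIL = 1e-3
_RHO_CAP = 0.9999  # keeps the correlation off the +/-1 boundary

#: conventional probit-to-logit slope rescaling
PROBIT_TO_LOGIT = 1.6


class ConvergenceError(RuntimeError):
    def __init__(self, msg, grad_norm=None, n_iter=None):
        super().__init__(msg)
        self.grad_norm = grad_norm
        self.n_iter = n_iter


@dataclass
class BivariateProbitFit:
    """Maximum-likelihood fit of a two-equation probit with correlated errors."""

    beta1: np.ndarray
    beta2: np.ndarray
    rho: float
    llf: float
    se_beta1: np.ndarray
    se_beta2: np.ndarray
    se_rho: float
    converged: bool
    grad_norm: float
    n_iter: int
    n: int
    constrain_equal: bool
    focal_index: int
    model_kind: str = "probit"
    _fingerprint: tuple = ()

    @property
    def focal_coefs(self) -> tuple:
        i = self.focal_index
        return float(self.beta1[i]), float(self.beta2[i])

    @property
    def focal_ses(self) -> tuple:
        i = self.focal_index
        return float(self.se_beta1[i]), float(self.se_beta2[i])


def _bvp_loglik_grad(theta, X, q1, q2, M):
    """Negative log-likelihood and gradient of the bivariate probit.

    ``theta`` packs the (possibly constrained) coefficients plus atanh(rho);
    ``M`` maps the sub-parameterisation to the full stacked (2p,) coefficient
    vector.
    """
    n, p = X.shape
    coef = M @ theta[:-1]
    z = theta[-1]
    rho = _RHO_CAP * np.tanh(z)
    b1, b2 = coef[:p], coef[p:]
    w1 = q1 * (X @ b1)
    w2 = q2 * (X @ b2)
    r = q1 * q2 * rho
    P = np.clip(bvn_cdf(w1, w2, r), _PHI_FLOOR, None)
    ll = float(np.sum(np.log(P)))

    sr = np.sqrt(np.clip(1.0 - r**2, 1e-12, None))
    phi1 = np.exp(-0.5 * w1**2) / np.sqrt(2 * np.pi)
    phi2 = np.exp(-0.5 * w2**2) / np.sqrt(2 * np.pi)
    g1 = q1 * phi1 * ndtr((w2 - r * w1) / sr) / P
    g2 = q2 * phi2 * ndtr((w1 - r * w2) / sr) / P
    grho = q1 * q2 * bvn_pdf(w1, w2, r) / P

    grad_full = np.concatenate([X.T @ g1, X.T @ g2])
    grad = np.empty(theta.size)
    grad[:-1] = M.T @ grad_full
    grad[-1] = float(np.sum(grho)) * _RHO_CAP * (1.0 - np.tanh(z) ** 2)
    return -ll, -grad


def _constraint_map(p: int, focal_index: int, constrain_equal: bool) -> np.ndarray:
    if not constrain_equal:
        return np.eye(2 * p)
    # shared focal coefficient, everything else equation-specific
    M = np.zeros((2 * p, 2 * p - 1))
    col = 0
    shared_col = None
    for eq in range(2):
        for j in range(p):
            row = eq * p + j
            if j == focal_index:
                if shared_col is None:
                    shared_col = col
                    col += 1
                M[row, shared_col] = 1.0
            else:
                M[row, col] = 1.0
                col += 1
    return M[:, : col]


def _univariate_probit_start(X, y):
    # a couple of Newton steps from zero are plenty for a starting value
    fit = fit_glm(X, y, family="binomial")
    return fit.beta / PROBIT_TO_LOGIT  # logit coefs rescaled to probit scale


def fit_bivariate_probit(
    y1,
    y2,
    X,
    constrain_equal: bool = False,
    focal_index: int = 0,
    max_iter: int = 300,
) -> BivariateProbitFit:
    """Fit the bivariate probit by quasi-Newton maximisation.

    ``X`` is the shared design matrix (include an intercept column);
    ``focal_index`` marks the exposure (CRP) column whose coefficient is
    shared across equations when ``constrain_equal``.  Starts from the two
    univariate probit fits and rho = 0.  Raises ConvergenceError when the
    optimiser stalls with a large gradient, or SeparationError propagated
    from degenerate starting fits.
    """
    X = np.asarray(X, float)
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n, p = X.shape
    if set(np.unique(y1)) - {0.0, 1.0} or set(np.unique(y2)) - {0.0, 1.0}:
        raise ValueError("both outcomes must be binary 0/1")
    if n <= 2 * p + 1:
        raise ValueError("more parameters than observations")
    q1 = 2.0 * y1 - 1.0
    q2 = 2.0 * y2 - 1.0
    M = _constraint_map(p, focal_index, constrain_equal)

    b1_0 = _univariate_probit_start(X, y1)
    b2_0 = _univariate_probit_start(X, y2)
    full0 = np.concatenate([b1_0, b2_0])
    # least-squares projection of the start onto the constrained space
    theta0 = np.append(np.linalg.lstsq(M, full0, rcond=None)[0], 0.0)

    res = optimize.minimize(
        _bvp_loglik_grad,
        theta0,
        args=(X, q1, q2, M),
        jac=True,
        method="BFGS",
        options={"gtol": _GRAD_TOL * n, "maxiter": max_iter},
    )
    _, g = _bvp_loglik_grad(res.x, X, q1, q2, M)
    gnorm = float(np.max(np.abs(g)) / n)
    if gnorm > _GRAD_FAIL:
        raise ConvergenceError(
            f"bivariate probit did not converge (mean-gradient {gnorm:.2e} "
            f"after {res.nit} iterations)",
            grad_norm=gnorm,
            n_iter=res.nit,
        )

    theta = res.x
    coef = M @ theta[:-1]
    rho = float(_RHO_CAP * np.tanh(theta[-1]))

    # observed information via central differences of the analytic gradient
    k = theta.size
    H = np.zeros((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(k):
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _bvp_loglik_grad(tp, X, q1, q2, M)
        _, gm = _bvp_loglik_grad(tm, X, q1, q2, M)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov_sub = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_sub = np.linalg.pinv(H)
    # delta method back to the full coefficient vector and rho
    J = np.zeros((2 * p + 1, k))
    J[: 2 * p, : k - 1] = M
    J[-1, -1] = _RHO_CAP * (1.0 - np.tanh(theta[-1]) ** 2)
    cov = J @ cov_sub @ J.T
    se_full = np.sqrt(np.maximum(np.diag(cov), 0.0))

    return BivariateProbitFit(
        beta1=coef[:p],
        beta2=coef[p:],
        rho=rho,
        llf=-res.fun,
        se_beta1=se_full[:p],
        se_beta2=se_full[p : 2 * p],
        se_rho=float(se_full[-1]),
        converged=gnorm < _GRAD_TOL,
        grad_norm=gnorm,
        n_iter=int(res.nit),
        n=n,
        constrain_equal=constrain_equal,
        focal_index=focal_index,
        model_kind="probit",
        _fingerprint=(n, float(y1.sum()), float(y2.sum())),
    )


# ---------------------------------------------------------------------------
# continuous-outcome analogue: bivariate Gaussian system


def fit_bivariate_gaussian(
    y1,
    y2,
    X,
    constrain_equal: bool = False,
    focal_index: int = 0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> BivariateProbitFit:
    """ML fit of a two-equation Gaussian system with correlated errors.

    With identical regressors the unconstrained MLE is equation-by-equation
    OLS; the equality-constrained fit is obtained by iterated feasible GLS,
    which converges to the MLE.  Returned in the same container as the
    probit fit so the LRT machinery is shared.
    """
    X = np.asarray(X, float)
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n, p = X.shape
    M = _constraint_map(p, focal_index, constrain_equal)
    k = M.shape[1]
    Y = np.concatenate([y1, y2])

    # stacked design: row-block per equation
    Xs = np.zeros((2 * n, 2 * p))
    Xs[:n, :p] = X
    Xs[n:, p:] = X
    Xd = Xs @ M

    Sigma = np.eye(2)
    coef_sub = np.linalg.lstsq(Xd, Y, rcond=None)[0]
    ll_old = -np.inf
    ll = 0.0
    cov_sub = None
    for _ in range(max_iter):
        Si = np.linalg.inv(Sigma)
        # GLS normal equations with error covariance Sigma (x) I_n
        A = np.zeros((k, k))
        b = np.zeros(k)
        blocks = [Xd[:n], Xd[n:]]
        ys = [y1, y2]
        for a in range(2):
            for c in range(2):
                A += Si[a, c] * blocks[a].T @ blocks[c]
                b += Si[a, c] * blocks[a].T @ ys[c]
        coef_sub = np.linalg.solve(A, b)
        e1 = y1 - blocks[0] @ coef_sub
        e2 = y2 - blocks[1] @ coef_sub
        E = np.column_stack([e1, e2])
        Sigma = E.T @ E / n
        sign, logdet = np.linalg.slogdet(Sigma)
        ll = -0.5 * n * (2 * np.log(2 * np.pi) + logdet + 2.0)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            cov_sub = np.linalg.inv(A)
            break
        ll_old = ll
    if cov_sub is None:
        cov_sub = np.linalg.inv(A)

    coef = M @ coef_sub
    cov = M @ cov_sub @ M.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rho = float(Sigma[0, 1] / np.sqrt(Sigma[0, 0] * Sigma[1, 1]))
    return BivariateProbitFit(
        beta1=coef[:p],
        beta2=coef[p:],
        rho=rho,
        llf=float(ll),
        se_beta1=se[:p],
        se_beta2=se[p : 2 * p],
        se_rho=float("nan"),
        converged=True,
        grad_norm=0.0,
        n_iter=0,
        n=n,
        constrain_equal=constrain_equal,
        focal_index=focal_index,
        model_kind="gaussian",
        _fingerprint=(n, float(y1.sum()), float(y2.sum())),
    )


# ---------------------------------------------------------------------------
# LRT and OR conversion


@dataclass
class SpecificityResult:
    lr: float
    df: int
    p: float
    or_dep: tuple  # (OR, ci_low, ci_high)
    or_anx: tuple
    rho: float
    analysis: str  # 'categorical' or 'continuous'


def lrt_specificity(
    free: BivariateProbitFit, constrained: BivariateProbitFit
) -> SpecificityResult:
    """LR test of equality of the two CRP coefficients (df = 1)."""
    if free._fingerprint != constrained._fingerprint:
        raise ValueError("free and constrained fits come from different data")
    if not constrained.constrain_equal or free.constrain_equal:
        raise ValueError("expected one free and one equality-constrained fit")
    lr = 2.0 * (free.llf - constrained.llf)
    if lr < -1e-6 * max(1.0, abs(free.llf)):
        raise ValueError("constrained log-likelihood exceeds free log-likelihood")
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, 1))
    b1, b2 = free.focal_coefs
    s1, s2 = free.focal_ses
    analysis = "categorical" if free.model_kind == "probit" else "continuous"
    if analysis == "categorical":
        or1 = probit_to_or(b1, s1)
        or2 = probit_to_or(b2, s2)
    else:
        or1 = tuple(
            float(np.exp(v)) for v in (b1, b1 - 1.96 * s1, b1 + 1.96 * s1)
        )
        or2 = tuple(
            float(np.exp(v)) for v in (b2, b2 - 1.96 * s2, b2 + 1.96 * s2)
        )
    return SpecificityResult(
        lr=float(lr), df=1, p=p, or_dep=or1, or_anx=or2, rho=free.rho,
        analysis=analysis,
    )


def probit_to_or(b: float, se: float):
    """Convert a probit coefficient to an odds ratio via the x1.6 rule.

    OR = exp(1.6 b) with CI exp(1.6 (b +/- 1.96 se)).
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    return (
        float(np.exp(PROBIT_TO_LOGIT * b)),
        float(np.exp(PROBIT_TO_LOGIT * (b - 1.96 * se))),
        float(np.exp(PROBIT_TO_LOGIT * (b + 1.96 * se))),
    )


# ---------------------------------------------------------------------------
# cohort-level drivers


def _specificity_design(cohort, model, outcomes):
    sub = _analysis_frame(cohort, "dep_score", model, "all")
    lc = np.log(sub["crp"].to_numpy(float))
    Z, _ = _model_design(sub, model)
    X = np.column_stack([np.ones(len(sub)), lc, Z])
    if outcomes == "categorical":
        y1 = (sub["dep_score"].to_numpy(float) >= 10).astype(float)
        y2 = (sub["anx_score"].to_numpy(float) >= 10).astype(float)
    else:
        y1 = transform_outcome(sub["dep_score"].to_numpy())
        y2 = transform_outcome(sub["anx_score"].to_numpy())
    return sub, X, y1, y2


def specificity_analysis(
    cohort, outcomes: str = "categorical", model: int = 4
) -> dict:
    """Full specificity analysis on a cohort: joint fit, LRT, mutual adjustment.

    ``outcomes='categorical'`` uses probable diagnoses in a bivariate probit;
    ``'continuous'`` uses transformed symptom scores in the Gaussian system.
    """
    if outcomes not in ("categorical", "continuous"):
        raise ValueError("outcomes must be 'categorical' or 'continuous'")
    _, X, y1, y2 = _specificity_design(cohort, model, outcomes)
    fitter = fit_bivariate_probit if outcomes == "categorical" else fit_bivariate_gaussian
    free = fitter(y1, y2, X, constrain_equal=False, focal_index=1)
    cons = fitter(y1, y2, X, constrain_equal=True, focal_index=1)
    res = lrt_specificity(free, cons)
    mutual = mutual_adjustment(cohort, model=model)
    return {
        "free": free,
        "constrained": cons,
        "lrt": res,
        "mutual_adjustment": mutual,
    }


def mutual_adjustment(cohort, model: int = 4) -> dict:
    """CRP estimates with each disorder adjusted for the other's symptoms.

    Model A regresses transformed depression score on log-CRP plus the
    anxiety score and covariates; model B vice versa.  A constant co-symptom
    column is dropped (degenerate covariate).  Returns exponentiated CRP
    coefficients with 95% CIs.
    """
    sub = _analysis_frame(cohort, "dep_score", model, "all")
    lc = np.log(sub["crp"].to_numpy(float))
    Z, _ = _model_design(sub, model)
    out = {}
    for label, ycol, adjcol in (
        ("dep_adj_anx", "dep_score", "anx_score"),
        ("anx_adj_dep", "anx_score", "dep_score"),
    ):
        y = transform_outcome(sub[ycol].to_numpy())
        adj = sub[adjcol].to_numpy(float)
        cols = [np.ones(len(sub)), lc]
        if np.ptp(adj) > 0:
            cols.append(adj)
        X = np.column_stack(cols + [Z]) if Z.size else np.column_stack(cols)
        fit = fit_glm(X, y, family="gaussian")
        b, se = float(fit.beta[1]), float(fit.se[1])
        out[label] = {
            "ratio": float(np.exp(b)),
            "ci_low": float(np.exp(b - 1.96 * se)),
            "ci_high": float(np.exp(b + 1.96 * se)),
            "p": float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else float("nan"),
        }
    return out
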