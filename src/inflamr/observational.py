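"""Dose-response association of CRP with depressive and anxiety outcomes.

Quantile (quintile/decile) construction on the analysis sample, covariate-
adjusted regression with four nested adjustment sets, floating absolute
risks (a variance for every exposure group, reference included, so that any
two groups can be compared without sharing the reference's uncertainty),
trend and quadratic-curvature tests, sex-interaction testing, and an
inverse-probability-weighted sensitivity analysis for outcome-dependent
survey participation.

Symptom scores enter regressions as log(score + 1); exponentiated
coefficients are reported as OR-style ratios.  Probable diagnoses (PHQ-9 or
GAD-7 >= 10) use logistic regression with ordinary odds ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._regress import fit_glm

logger = logging.getLogger(__name__)

#: adjustment sets for models 1-4 (cumulative)
MODEL_COVARIATES = {
    1: [],
    2: ["age", "sex", "bmi"],
    3: ["age", "sex", "bmi", "smoking", "alcohol", "activity", "ethnicity", "tdi"],
    4: [
        "age",
        "sex",
        "bmi",
        "smoking",
        "alcohol",
        "activity",
        "ethnicity",
        "tdi",
        "diabetes",
        "cvd",
    ],
}

_CONTINUOUS_OUTCOMES = ("dep_score", "anx_score")
_BINARY_OUTCOMES = ("dep_dx", "gad_dx")


# ---------------------------------------------------------------------------
# quantile machinery


@dataclass
class QuantileAssignment:
    K: int
    cut_points: np.ndarray  # K-1 strictly increasing CRP values (mg/L)
    group_index: np.ndarray  # per-participant 1..K
    group_medians: np.ndarray  # mg/L
    group_sizes: np.ndarray


def assign_quantiles(crp: np.ndarray, K: int) -> QuantileAssignment:
    """Split positive CRP values into K near-equal groups.

    Cut points are empirical quantiles of the analysis sample; a value tied
    with a cut point goes to the lower group.
    """
    x = np.asarray(crp, float)
    if K < 2:
        raise ValueError("K must be at least 2")
    if np.any(~(x > 0)):
        raise ValueError("all CRP values must be positive")
    if len(np.unique(x)) < K:
        raise ValueError("K exceeds the number of distinct CRP values")
    cuts = np.quantile(x, np.arange(1, K) / K, method="inverted_cdf")
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("quantile cut points are not strictly increasing "
                         "(too many ties for the requested K)")
    idx = np.searchsorted(cuts, x, side="left") + 1
    medians = np.array([np.median(x[idx == k]) for k in range(1, K + 1)])
    sizes = np.bincount(idx, minlength=K + 1)[1:]
    return QuantileAssignment(K, cuts, idx, medians, sizes)


def transform_outcome(score) -> np.ndarray:
    """log(score + 1) transform for right-skewed symptom counts."""
    s = np.asarray(score, float)
    if np.any(s < 0):
        raise ValueError("scores must be non-negative")
    return np.log1p(s)


# ---------------------------------------------------------------------------
# floating absolute risks


def floated_variances(V: np.ndarray, refine: bool = False, eps: float = 1e-12):
    """Floated variances lambda_0..lambda_{K-1} from the covariance of the
    K-1 non-reference log-OR contrasts.

    lambda_0 (reference) is the mean off-diagonal covariance — exact under
    compound symmetry, where Var(beta_i - beta_j) = lambda_i + lambda_j
    holds identically.  ``refine`` replaces the heuristic with a
    least-squares fit of lambda_i + lambda_j to all pairwise contrast
    variances (reference included).
    """
    V = np.asarray(V, float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("V must be a square matrix")
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("V must be symmetric")
    evals = np.linalg.eigvalsh(0.5 * (V + V.T))
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("V must be positive semi-definite")
    m = V.shape[0]
    warn_floor = False
    if m == 1:
        lam = np.array([0.0, float(V[0, 0])])
    else:
        off = V[~np.eye(m, dtype=bool)]
        lam0 = float(np.mean(off))
        lam_rest = np.diag(V) - lam0
        if np.any(lam_rest <= 0):
            warn_floor = True
        lam = np.concatenate([[max(lam0, 0.0)], np.maximum(lam_rest, eps)])
    if refine and m >= 2:
        # pairwise contrast variances, reference (index 0) included
        rows, targets = [], []
        K = m + 1
        for i in range(K):
            for j in range(i + 1, K):
                r = np.zeros(K)
                r[i] = 1.0
                r[j] = 1.0
                if i == 0:
                    d = V[j - 1, j - 1]
                else:
                    d = V[i - 1, i - 1] + V[j - 1, j - 1] - 2 * V[i - 1, j - 1]
                rows.append(r)
                targets.append(d)
        sol = optimize.lsq_linear(
            np.array(rows), np.array(targets), bounds=(eps, np.inf)
        )
        lam = sol.x
    if warn_floor:
        logger.warning("floated variance floored at eps for some groups")
    return lam


# ---------------------------------------------------------------------------
# design-matrix construction


def _model_design(cohort: pd.DataFrame, model: int, drop_sex: bool = False):
    """Indicator-coded covariate matrix (no intercept column) for models 1-4."""
    if model not in MODEL_COVARIATES:
        raise ValueError("adjustment model must be 1, 2, 3 or 4")
    cols, names = [], []
    for cov in MODEL_COVARIATES[model]:
        if cov == "sex":
            if drop_sex:
                continue
            cols.append((cohort["sex"] == "female").to_numpy(float))
            names.append("female")
        elif cov == "smoking":
            for lev in ("current", "ex"):
                cols.append((cohort["smoking"] == lev).to_numpy(float))
                names.append(f"smoking_{lev}")
        elif cov == "alcohol":
            for lev in ("occasional", "regular"):
                cols.append((cohort["alcohol"] == lev).to_numpy(float))
                names.append(f"alcohol_{lev}")
        elif cov == "activity":
            for lev in (2, 3, 4):
                cols.append((cohort["activity"] == lev).to_numpy(float))
                names.append(f"activity_{lev}")
        elif cov == "ethnicity":
            cols.append((cohort["ethnicity"] != "white").to_numpy(float))
            names.append("nonwhite")
        else:
            cols.append(cohort[cov].to_numpy(float))
            names.append(cov)
    if cols:
        Z = np.column_stack(cols)
    else:
        Z = np.empty((len(cohort), 0))
    # drop constant covariates (degenerate within strata/subsets)
    keep = [i for i in range(Z.shape[1]) if np.ptp(Z[:, i]) > 0]
    return Z[:, keep], [names[i] for i in keep]


def _analysis_frame(cohort: pd.DataFrame, outcome: str, model: int,
                    sex_stratum: str = "all") -> pd.DataFrame:
    needed = {"crp", "dep_score", "anx_score", "sex"} | set(
        c for c in MODEL_COVARIATES[model] if c != "sex"
    )
    sub = cohort.dropna(subset=[c for c in needed if c in cohort.columns])
    if sex_stratum == "women":
        sub = sub[sub["sex"] == "female"]
    elif sex_stratum == "men":
        sub = sub[sub["sex"] == "male"]
    elif sex_stratum != "all":
        raise ValueError(f"unknown sex stratum {sex_stratum!r}")
    if len(sub) == 0:
        raise ValueError(f"empty analysis stratum {sex_stratum!r}")
    return sub


def _outcome_and_family(sub: pd.DataFrame, outcome: str):
    if outcome in _CONTINUOUS_OUTCOMES:
        return transform_outcome(sub[outcome].to_numpy()), "gaussian"
    if outcome == "dep_dx":
        return (sub["dep_score"].to_numpy(float) >= 10).astype(float), "binomial"
    if outcome == "gad_dx":
        return (sub["anx_score"].to_numpy(float) >= 10).astype(float), "binomial"
    raise ValueError(f"unknown outcome {outcome!r}")


# ---------------------------------------------------------------------------
# main fits


@dataclass
class QuantileAssociationResult:
    """Per-quantile ORs with floated CIs plus trend/continuous summaries."""

    outcome: str
    K: int
    model: int
    sex_stratum: str
    n: int
    quantiles: QuantileAssignment
    beta: np.ndarray  # length K, reference first (0 by construction)
    lambdas: np.ndarray  # floated variances, length K
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    trend_beta: float
    trend_se: float
    trend_or: float
    trend_ci: tuple
    trend_p: float
    continuous_beta: float
    continuous_se: float
    continuous_or: float
    continuous_ci: tuple
    continuous_p: float
    ipw: bool = False
    cov_nonref: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantile": np.arange(1, self.K + 1),
                "median_crp": self.quantiles.group_medians,
                "n": self.quantiles.group_sizes,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def fit_doseresponse(
    cohort: pd.DataFrame,
    outcome: str = "dep_score",
    K: int = 5,
    model: int = 1,
    sex_stratum: str = "all",
    ipw_weights: np.ndarray | None = None,
) -> QuantileAssociationResult:
    """Dose-response association of CRP with an outcome.

    Fits three regressions on the analysis sample: quantile-indicator,
    quantile-index trend, and continuous log-CRP; continuous outcomes use
    linear regression on log(score+1), binary outcomes logistic regression.
    Floated variances give every quantile (reference included) its own CI.
    """
    sub = _analysis_frame(cohort, outcome, model, sex_stratum)
    w = None
    if ipw_weights is not None:
        w = np.asarray(ipw_weights, float)
        if w.shape[0] == len(cohort):
            w = w[cohort.index.get_indexer(sub.index)]
        mask = w > 0
        sub = sub[mask]
        w = w[mask]
    y, family = _outcome_and_family(sub, outcome)
    robust = w is not None

    qa = assign_quantiles(sub["crp"].to_numpy(float), K)
    Z, _ = _model_design(sub, model, drop_sex=sex_stratum != "all")
    n = len(sub)

    # quantile-indicator fit (reference = group 1)
    D = np.column_stack([(qa.group_index == k).astype(float) for k in range(2, K + 1)])
    X = np.column_stack([np.ones(n), D, Z])
    fit = fit_glm(X, y, family=family, weights=w, robust=robust)
    bq = fit.beta[1:K]
    Vq = fit.cov[1:K, 1:K]
    lam = floated_variances(Vq)
    beta_all = np.concatenate([[0.0], bq])
    half = 1.96 * np.sqrt(lam)
    ors = np.exp(beta_all)
    ci_low = np.exp(beta_all - half)
    ci_high = np.exp(beta_all + half)

    # trend: quantile number as predictor
    Xt = np.column_stack([np.ones(n), qa.group_index.astype(float), Z])
    ft = fit_glm(Xt, y, family=family, weights=w, robust=robust)
    tb, tse = float(ft.beta[1]), float(ft.se[1])
    tp = float(2 * stats.norm.sf(abs(tb / tse)))

    # continuous log-CRP
    Xc = np.column_stack([np.ones(n), np.log(sub["crp"].to_numpy(float)), Z])
    fc = fit_glm(Xc, y, family=family, weights=w, robust=robust)
    cb, cse = float(fc.beta[1]), float(fc.se[1])
    cp = float(2 * stats.norm.sf(abs(cb / cse)))

    return QuantileAssociationResult(
        outcome=outcome,
        K=K,
        model=model,
        sex_stratum=sex_stratum,
        n=n,
        quantiles=qa,
        beta=beta_all,
        lambdas=lam,
        odds_ratios=ors,
        ci_low=ci_low,
        ci_high=ci_high,
        trend_beta=tb,
        trend_se=tse,
        trend_or=float(np.exp(tb)),
        trend_ci=(float(np.exp(tb - 1.96 * tse)), float(np.exp(tb + 1.96 * tse))),
        trend_p=tp,
        continuous_beta=cb,
        continuous_se=cse,
        continuous_or=float(np.exp(cb)),
        continuous_ci=(float(np.exp(cb - 1.96 * cse)), float(np.exp(cb + 1.96 * cse))),
        continuous_p=cp,
        ipw=ipw_weights is not None,
        cov_nonref=Vq,
    )


def test_linearity(
    cohort: pd.DataFrame,
    outcome: str = "dep_score",
    model: int = 4,
    sex_stratum: str = "all",
    ipw_weights: np.ndarray | None = None,
):
    """Quadratic-curvature test: add (log CRP)^2 to the continuous model.

    Returns (quadratic coefficient, Wald p-value).
    """
    sub = _analysis_frame(cohort, outcome, model, sex_stratum)
    w = _subset_weights(cohort, sub, ipw_weights)
    if w is not None:
        sub, w = sub[w > 0], w[w > 0]
    y, family = _outcome_and_family(sub, outcome)
    lc = np.log(sub["crp"].to_numpy(float))
    lc_c = lc - lc.mean()  # centred to decorrelate the linear and square terms
    Z, _ = _model_design(sub, model, drop_sex=sex_stratum != "all")
    X = np.column_stack([np.ones(len(sub)), lc_c, lc_c**2, Z])
    fit = fit_glm(X, y, family=family, weights=w, robust=w is not None)
    b, se = float(fit.beta[2]), float(fit.se[2])
    return b, float(2 * stats.norm.sf(abs(b / se)))


def test_sex_interaction(
    cohort: pd.DataFrame,
    outcome: str = "dep_score",
    model: int = 4,
    ipw_weights: np.ndarray | None = None,
):
    """Sex x log-CRP interaction with per-sex stratified estimates.

    Returns (interaction coefficient, p, {'women': fit, 'men': fit}) where
    each stratified entry is (beta, se) for log-CRP.
    """
    if cohort["sex"].nunique() < 2:
        raise ValueError("sex-interaction test requires both sexes")
    sub = _analysis_frame(cohort, outcome, model, "all")
    w = _subset_weights(cohort, sub, ipw_weights)
    if w is not None:
        sub, w = sub[w > 0], w[w > 0]
    y, family = _outcome_and_family(sub, outcome)
    lc = np.log(sub["crp"].to_numpy(float))
    fem = (sub["sex"] == "female").to_numpy(float)
    Z, names = _model_design(sub, model, drop_sex=False)
    if model == 1:
        Z = np.column_stack([Z, fem])
    X = np.column_stack([np.ones(len(sub)), lc, lc * fem, Z])
    fit = fit_glm(X, y, family=family, weights=w, robust=w is not None)
    b, se = float(fit.beta[2]), float(fit.se[2])
    p = float(2 * stats.norm.sf(abs(b / se)))

    strat = {}
    for label in ("women", "men"):
        r = fit_doseresponse(
            cohort, outcome=outcome, K=5, model=model, sex_stratum=label,
            ipw_weights=ipw_weights,
        )
        strat[label] = (r.continuous_beta, r.continuous_se)
    return b, p, strat


def _subset_weights(cohort, sub, ipw_weights):
    if ipw_weights is None:
        return None
    w = np.asarray(ipw_weights, float)
    if w.shape[0] == len(cohort):
        w = w[cohort.index.get_indexer(sub.index)]
    if w.shape[0] != len(sub):
        raise ValueError("ipw_weights length does not match cohort")
    return w


# ---------------------------------------------------------------------------
# inverse probability of selection weighting


@dataclass
class IPWWeights:
    """Estimated selection probabilities and inverse-probability weights.

    ``weights`` is full-cohort length: 1/p_hat for selected rows, 0 for
    unselected rows (so weighted fits over the full table equal weighted
    fits on the selected subset).
    """

    p_hat: np.ndarray
    weights: np.ndarray
    coefficients: dict
    n_truncated: int
    stabilized: bool
    selected_fraction: float

    def for_selected(self) -> np.ndarray:
        return self.weights[self.weights > 0]


DEFAULT_SELECTION_COVARIATES = ("dep_score", "anx_score", "age", "sex", "tdi")


def fit_selection_model(
    cohort: pd.DataFrame,
    covariates=DEFAULT_SELECTION_COVARIATES,
    stabilized: bool = False,
    floor: float = 1e-3,
) -> IPWWeights:
    """Logistic model of survey participation; weights = 1/p_hat.

    Requires both selected and unselected rows.  Probabilities below
    ``floor`` are truncated (count reported) to cap weight variability;
    ``stabilized`` multiplies weights by the marginal selection fraction.
    """
    if "selected" not in cohort.columns:
        raise ValueError("cohort has no 'selected' column")
    sel = cohort["selected"].to_numpy(float)
    if sel.min() == sel.max():
        raise ValueError("selection model needs both selected and unselected rows")
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for c in covariates:
        if c == "sex":
            cols.append((cohort["sex"] == "female").to_numpy(float))
            names.append("female")
        else:
            cols.append(cohort[c].to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    fit = fit_glm(X, sel, family="binomial")
    from scipy.special import expit

    p_hat = expit(X @ fit.beta)
    n_trunc = int(np.sum(p_hat < floor))
    p_hat = np.clip(p_hat, floor, 1.0)
    w = np.where(sel > 0, 1.0 / p_hat, 0.0)
    frac = float(sel.mean())
    if stabilized:
        w = w * frac
    return IPWWeights(
        p_hat=p_hat,
        weights=w,
        coefficients=dict(zip(names, fit.beta.tolist())),
        n_truncated=n_trunc,
        stabilized=stabilized,
        selected_fraction=frac,
    )


# ---------------------------------------------------------------------------
# figure


def plot_floated_risks(result: QuantileAssociationResult, path=None, ax=None):
    """OR (log scale) vs group-median CRP with floated 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = result.quantiles.group_medians
    ax.errorbar(
        x,
        result.odds_ratios,
        yerr=[
            result.odds_ratios - result.ci_low,
            result.ci_high - result.odds_ratios,
        ],
        fmt="o",
        capsize=3,
    )
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("median CRP (mg/L)")
    ax.set_ylabel("odds ratio (floated 95% CI)")
    ax.set_title(f"{result.outcome}, model {result.model}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
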