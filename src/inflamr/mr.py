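"""Summary-based Mendelian randomisation.

Implements the building blocks used to probe whether inflammation causally
affects depressive/anxiety outcomes: per-SNP Wald ratios, the
inverse-variance-weighted (IVW) estimator (a weighted regression of
SNP-outcome on SNP-exposure associations through the origin), Cochran's Q
heterogeneity statistic as a pleiotropy screen, allele harmonisation between
exposure and outcome association tables, per-SNP association estimation on
individual-level cohorts (1-sample designs, optionally sex-stratified and/or
inverse-probability weighted), and an orchestrator combining the stages.

Conventions
-----------
Exposure units: the CRP exposure is log-CRP (mg/L); the IL-6 exposure is
genetically predicted IL-6 activity read out through CRP, i.e. log-CRP shifts
induced by IL6R-region variants.  Symptom-score outcomes are modelled on the
multiplicative (log-mean) scale, binary probable diagnoses on the log-odds
scale, so exponentiated IVW estimates are odds-ratio-style quantities per
unit exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._regress import fit_glm

logger = logging.getLogger(__name__)

INSTRUMENT_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: EAF window inside which a palindromic SNP is considered un-alignable.
PALINDROME_EAF_LOW = 0.42
PALINDROME_EAF_HIGH = 0.58


# ---------------------------------------------------------------------------
# instrument-table validation


def validate_instruments(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an instrument table (GWAS summary-statistic layout).

    Required columns: snp, effect_allele, other_allele, eaf, beta, se, n.
    Rows with non-positive SE or malformed alleles are rejected (logged);
    duplicated variant ids raise.
    """
    missing = [c for c in INSTRUMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"instrument table missing columns: {missing}")
    tab = table.copy()
    if tab["snp"].duplicated().any():
        dups = tab.loc[tab["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"duplicated variant ids in instrument table: {dups}")
    ok_allele = tab["effect_allele"].isin(_COMPLEMENT) & tab["other_allele"].isin(
        _COMPLEMENT
    )
    ok = (
        ok_allele
        & (tab["effect_allele"] != tab["other_allele"])
        & (tab["se"] > 0)
        & tab["beta"].notna()
    )
    for _, row in tab.loc[~ok].iterrows():
        logger.warning("dropping instrument %s: invalid alleles or se", row["snp"])
    return tab.loc[ok].reset_index(drop=True)


# ---------------------------------------------------------------------------
# core estimators


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float):
    """Per-SNP causal estimate beta_y / beta_x with first-order SE se_y/|beta_x|.

    The first-order variance ignores uncertainty in the SNP-exposure
    association, the standard choice for strong instruments.
    """
    if beta_x == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0 (degenerate instrument)")
    if se_y <= 0:
        raise ValueError("se_y must be positive")
    return beta_y / beta_x, se_y / abs(beta_x)


@dataclass
class MRResult:
    """IVW estimate with per-SNP diagnostics.

    ``beta`` is on the log-OR / log-ratio scale; ``odds_ratio`` and its CI
    are its exponential.  Q is Cochran's heterogeneity statistic over the
    per-SNP Wald ratios (NaN when fewer than two instruments).
    """

    beta: float
    se: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    q: float
    q_df: int
    q_p: float
    n_snps: int
    model: str  # 'fixed' or 'random'
    snp_ids: list = field(default_factory=list)
    wald_ratios: np.ndarray | None = None
    wald_se: np.ndarray | None = None
    design: str = ""
    exposure: str = ""
    outcome: str = ""
    stratum: str = "all"
    ipw: bool = False

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "stratum": self.stratum,
            "ipw": self.ipw,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "cochran_q": None if np.isnan(self.q) else self.q,
            "q_df": self.q_df,
            "q_p": None if np.isnan(self.q_p) else self.q_p,
            "n_snps": self.n_snps,
            "model": self.model,
        }


def ivw(
    beta_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    snp_ids=None,
    random_effects: bool = False,
) -> MRResult:
    """Inverse-variance-weighted estimate from aligned summary statistics.

    Weighted regression of beta_y on beta_x through the origin with weights
    1/se_y^2; algebraically the w_j-weighted mean of the per-SNP Wald ratios
    with w_j = beta_x_j^2 / se_y_j^2.  ``random_effects`` applies the
    multiplicative random-effects inflation max(1, sqrt(Q/(J-1))) to the SE.
    """
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    J = beta_x.size
    if J == 0:
        raise ValueError("ivw requires at least one instrument")
    if np.any(se_y <= 0):
        raise ValueError("all se_y must be positive")
    if np.any(beta_x == 0):
        raise ValueError("beta_x contains zeros (degenerate instruments)")

    w = beta_x**2 / se_y**2
    theta = beta_y / beta_x
    beta_ivw = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)

    if J >= 2:
        q = float(np.sum(w * (theta - beta_ivw) ** 2))
        q_df = J - 1
        q_p = float(stats.chi2.sf(q, q_df))
    else:
        q, q_df, q_p = float("nan"), 0, float("nan")

    model = "fixed"
    se = se_fixed
    if random_effects and J >= 2:
        se = se_fixed * max(1.0, np.sqrt(q / q_df))
        model = "random"

    z = beta_ivw / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (beta_ivw - 1.96 * se, beta_ivw + 1.96 * se)
    return MRResult(
        beta=beta_ivw,
        se=se,
        p=p,
        odds_ratio=float(np.exp(beta_ivw)),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        q=q,
        q_df=q_df,
        q_p=q_p,
        n_snps=J,
        model=model,
        snp_ids=list(snp_ids) if snp_ids is not None else [],
        wald_ratios=theta,
        wald_se=se_y / np.abs(beta_x),
    )


def cochran_q(beta_x, beta_y, se_y, beta_ivw: float):
    """Cochran's Q = sum_j w_j (theta_j - beta_ivw)^2 with first-order weights.

    Returns (Q, df, p); Q is NaN with df 0 for a single instrument.
    """
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    J = beta_x.size
    if J < 2:
        return float("nan"), 0, float("nan")
    w = beta_x**2 / se_y**2
    theta = beta_y / beta_x
    q = float(np.sum(w * (theta - beta_ivw) ** 2))
    return q, J - 1, float(stats.chi2.sf(q, J - 1))


# ---------------------------------------------------------------------------
# harmonisation


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome associations to the exposure's effect alleles.

    Rules: matching allele pairs pass through; swapped effect/other alleles
    flip the outcome beta and complement its EAF; opposite-strand codings are
    complemented first.  Palindromic (A/T, C/G) variants are aligned by
    allele frequency when both EAFs are available and outside
    (0.42, 0.58), otherwise dropped.  Any other allele mismatch drops the
    SNP.  The result carries columns beta_x, se_x, beta_y, se_y plus
    bookkeeping counts in ``result.attrs['harmonization']``.
    """
    exp = exposure.set_index("snp")
    out = outcome.set_index("snp")
    shared = exp.index.intersection(out.index)
    rows = []
    n_flipped = n_dropped = n_palindromic = 0
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_y, eaf_y = float(o["beta"]), o.get("eaf", np.nan)

        if _is_palindromic(ea_e, oa_e):
            n_palindromic += 1
            eaf_x = e.get("eaf", np.nan)
            if (
                pd.isna(eaf_x)
                or pd.isna(eaf_y)
                or PALINDROME_EAF_LOW < eaf_x < PALINDROME_EAF_HIGH
                or PALINDROME_EAF_LOW < eaf_y < PALINDROME_EAF_HIGH
            ):
                n_dropped += 1
                logger.info("dropping palindromic SNP %s: ambiguous frequency", snp)
                continue
            # same-side frequencies mean the effect alleles agree
            if (eaf_x < 0.5) != (eaf_y < 0.5):
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
                n_flipped += 1
        else:
            pair_o = (ea_o, oa_o)
            if pair_o == (ea_e, oa_e):
                pass
            elif pair_o == (oa_e, ea_e):
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if not pd.isna(eaf_y) else eaf_y
                n_flipped += 1
            elif pair_o == (_COMPLEMENT[ea_e], _COMPLEMENT[oa_e]):
                pass  # strand flip, same orientation
            elif pair_o == (_COMPLEMENT[oa_e], _COMPLEMENT[ea_e]):
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if not pd.isna(eaf_y) else eaf_y
                n_flipped += 1
            else:
                n_dropped += 1
                logger.info("dropping SNP %s: allele pair mismatch", snp)
                continue
        rows.append(
            {
                "snp": snp,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "eaf": e.get("eaf", np.nan),
                "beta_x": float(e["beta"]),
                "se_x": float(e["se"]),
                "beta_y": beta_y,
                "se_y": float(o["se"]),
            }
        )
    aligned = pd.DataFrame(
        rows,
        columns=[
            "snp",
            "effect_allele",
            "other_allele",
            "eaf",
            "beta_x",
            "se_x",
            "beta_y",
            "se_y",
        ],
    )
    aligned.attrs["harmonization"] = {
        "n_shared": int(len(shared)),
        "n_flipped": n_flipped,
        "n_dropped": n_dropped,
        "n_palindromic": n_palindromic,
    }
    return aligned


# ---------------------------------------------------------------------------
# per-SNP association estimation on a cohort (1-sample designs)


_DEFAULT_MR_COVARIATES = ("age", "sex")


def _covariate_matrix(cohort: pd.DataFrame, covariates, stratum: str) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for c in covariates:
        if c == "sex":
            if stratum != "all":
                continue  # constant within a sex stratum
            cols.append((cohort["sex"] == "female").to_numpy(float))
        else:
            cols.append(cohort[c].to_numpy(float))
    return np.column_stack(cols)


def _subset_stratum(cohort: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return cohort
    if stratum in ("women", "female"):
        return cohort[cohort["sex"] == "female"]
    if stratum in ("men", "male"):
        return cohort[cohort["sex"] == "male"]
    raise ValueError(f"unknown stratum {stratum!r}")


def _outcome_vector(cohort: pd.DataFrame, variable: str):
    """Return (values, family) for an analysis variable."""
    if variable == "log_crp":
        return np.log(cohort["crp"].to_numpy(float)), "gaussian"
    if variable in ("dep_score", "anx_score"):
        # count scores: log-link (quasi-Poisson) model, effects on the
        # multiplicative symptom-score scale
        return cohort[variable].to_numpy(float), "poisson"
    if variable == "dep_dx":
        return (cohort["dep_score"].to_numpy(float) >= 10).astype(float), "binomial"
    if variable == "gad_dx":
        return (cohort["anx_score"].to_numpy(float) >= 10).astype(float), "binomial"
    raise ValueError(f"unknown analysis variable {variable!r}")


def estimate_snp_associations(
    cohort: pd.DataFrame,
    variable: str,
    snp_columns=None,
    covariates=_DEFAULT_MR_COVARIATES,
    stratum: str = "all",
    ipw_weights: np.ndarray | None = None,
    allele_info: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Estimate per-SNP associations of genotype dosage with ``variable``.

    One regression per SNP of the outcome on dosage plus covariates:
    linear for log-CRP, log-link quasi-Poisson (robust SE) for symptom
    scores, logistic for probable diagnoses.  Symptom-score effects are
    rescaled to the latent (ceiling-free) multiplicative scale by the
    attenuation factor of a NB-lognormal measurement model fitted to the
    marginal score distribution (bounded instruments compress multiplicative
    effects near their maximum); the factor is reported in
    ``table.attrs['ceiling_attenuation']``.  ``ipw_weights`` (full-cohort
    length, zero/ignored for unselected rows) triggers weighted fits with
    sandwich SEs.  Monomorphic SNPs are dropped with a log entry.

    Returns a table in the GWAS summary-statistic layout (beta per effect
    allele, the dosage-counted allele).
    """
    if snp_columns is None:
        snp_columns = [c for c in cohort.columns if c.startswith("g_")]
    sub = _subset_stratum(cohort, stratum)
    idx = sub.index
    y, family = _outcome_vector(sub, variable)
    Z = _covariate_matrix(sub, covariates, stratum)
    w = None
    if ipw_weights is not None:
        w = np.asarray(ipw_weights, float)
        if w.shape[0] == len(cohort):
            w = w[cohort.index.get_indexer(idx)]
        if w.shape[0] != len(sub):
            raise ValueError("ipw_weights length does not match cohort")
    robust = (w is not None) or (family == "poisson")

    ceiling = 1.0
    if family == "poisson":
        from ._ceiling import estimate_ceiling_correction

        cap = 27 if variable == "dep_score" else 21
        ceiling = estimate_ceiling_correction(y, cap, weights=w)

    rows = []
    for snp in snp_columns:
        g = sub[snp].to_numpy(float)
        if np.all(g == g[0]):
            logger.warning("dropping monomorphic SNP %s", snp)
            continue
        X = np.column_stack([g, Z])
        fit = fit_glm(X, y, family=family, weights=w, robust=robust)
        eaf = float(np.mean(g) / 2.0)
        row = {
            "snp": snp,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": float(fit.beta[0]) / ceiling,
            "se": float(fit.se[0]) / ceiling,
            "n": int(len(sub)),
        }
        if allele_info is not None and snp in set(allele_info["snp"]):
            ai = allele_info.set_index("snp").loc[snp]
            row["effect_allele"] = ai["effect_allele"]
            row["other_allele"] = ai["other_allele"]
        rows.append(row)
    tab = pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)
    tab.attrs["variable"] = variable
    tab.attrs["stratum"] = stratum
    tab.attrs["ipw"] = ipw_weights is not None
    tab.attrs["ceiling_attenuation"] = ceiling
    return tab


# ---------------------------------------------------------------------------
# orchestration


def _region_snps(cohort: pd.DataFrame, exposure: str):
    prefix = "g_CRP_" if exposure.lower() == "crp" else "g_IL6R_"
    snps = [c for c in cohort.columns if c.startswith(prefix)]
    if not snps:
        raise ValueError(f"no genotype columns with prefix {prefix!r} in cohort")
    return snps


def run_mr(
    design: str,
    exposure: str,
    outcome: str,
    cohort: pd.DataFrame | None = None,
    instruments: pd.DataFrame | None = None,
    stratum: str = "all",
    ipw_weights: np.ndarray | None = None,
    covariates=_DEFAULT_MR_COVARIATES,
    random_effects: bool = False,
) -> MRResult:
    """Run a full MR analysis: estimate/ingest associations, harmonise, IVW, Q.

    design='one_sample': SNP-exposure and SNP-outcome associations are both
    estimated on ``cohort``.  design='two_sample': SNP-exposure associations
    come from ``instruments`` (external summary statistics); SNP-outcome
    associations are estimated on the cohort.  exposure 'crp' uses the
    CRP-region variants with log-CRP as exposure; exposure 'il6' uses the
    IL6R-region variants with CRP as the downstream readout of IL-6 activity,
    so estimates are per unit genetically predicted IL-6 activity on the
    readout scale.
    """
    if design not in ("one_sample", "two_sample"):
        raise ValueError(f"unknown design {design!r}")
    if cohort is None:
        raise ValueError("a cohort is required for SNP-outcome estimation")
    snps = _region_snps(cohort, exposure)
    allele_info = None
    if design == "one_sample":
        exp_assoc = estimate_snp_associations(
            cohort, "log_crp", snp_columns=snps, covariates=covariates,
            stratum=stratum,
        )
    else:
        if instruments is None:
            raise ValueError("two_sample design requires an instrument table")
        exp_assoc = validate_instruments(instruments)
        exp_assoc = exp_assoc[exp_assoc["snp"].isin(snps)].reset_index(drop=True)
        # cohort dosages count the instrument table's effect alleles, so the
        # outcome table inherits that orientation
        allele_info = exp_assoc[["snp", "effect_allele", "other_allele"]]
    out_assoc = estimate_snp_associations(
        cohort, outcome, snp_columns=snps, covariates=covariates, stratum=stratum,
        ipw_weights=ipw_weights, allele_info=allele_info,
    )

    if design == "one_sample":
        # both tables share dosage-coded alleles: already aligned
        aligned = pd.merge(
            exp_assoc.rename(columns={"beta": "beta_x", "se": "se_x"})[
                ["snp", "beta_x", "se_x"]
            ],
            out_assoc.rename(columns={"beta": "beta_y", "se": "se_y"})[
                ["snp", "beta_y", "se_y"]
            ],
            on="snp",
        )
    else:
        aligned = harmonize(exp_assoc, out_assoc)
    if len(aligned) == 0:
        raise ValueError("no instruments remain after harmonisation")
    res = ivw(
        aligned["beta_x"].to_numpy(),
        aligned["beta_y"].to_numpy(),
        aligned["se_y"].to_numpy(),
        snp_ids=aligned["snp"].tolist(),
        random_effects=random_effects,
    )
    res.design = design
    res.exposure = exposure
    res.outcome = outcome
    res.stratum = stratum
    res.ipw = ipw_weights is not None
    return res
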