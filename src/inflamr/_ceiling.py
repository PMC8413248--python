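"""Ceiling-effect correction for bounded symptom scores.

PHQ-9 and GAD-7 sum scores are right-bounded at the instrument maximum, so
a log-linear mean model fitted to observed scores under-states multiplicative
effects: individuals pushed past the ceiling register no further increase.
The correction here fits a negative-binomial-lognormal measurement model to
the marginal score distribution (score ~ NB with log-mean a + sigma*Z,
Z standard normal, truncated at the cap), then computes the local
attenuation factor

    c = d log E[min(S, cap)] / d log E[S]

by quadrature under the fitted model.  Per-unit multiplicative effects
estimated on the observed (capped) scale are divided by c to recover the
latent (ceiling-free) scale.  For the default cohort calibration c is about
0.94-0.95; it approaches 1 when the ceiling mass vanishes.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special

_N_NODES = 61
_NODES, _WTS = hermegauss(_N_NODES)
_WTS = _WTS / np.sqrt(2.0 * np.pi)


def _nb_pmf_matrix(mu: np.ndarray, r: float, cap: int) -> np.ndarray:
    """NB pmf for k = 0..cap-1 at each mu (rows: mu, cols: k)."""
    k = np.arange(cap)
    lg = (
        special.gammaln(k + r)
        - special.gammaln(r)
        - special.gammaln(k + 1)
        + r * np.log(r / (r + mu))[:, None]
        + k * np.log(mu / (r + mu))[:, None]
    )
    return np.exp(lg)


def _cell_probs(a: float, sigma: float, r: float, cap: int) -> np.ndarray:
    mu = np.exp(np.clip(a + sigma * _NODES, -30.0, 30.0))
    cells = _WTS @ _nb_pmf_matrix(mu, r, cap)
    return np.append(cells, max(1.0 - cells.sum(), 1e-300))


def fit_score_measurement_model(
    scores: np.ndarray, cap: int, weights: np.ndarray | None = None
):
    """ML fit of the NB-lognormal model to the (optionally weighted) histogram.

    Returns (a, sigma, r): marginal log-mean intercept, latent SD and NB size.
    """
    scores = np.asarray(scores)
    counts = np.bincount(
        scores.astype(int), weights=weights, minlength=cap + 1
    )[: cap + 1].astype(float)

    def nll(p):
        a, ls, lr = p
        probs = _cell_probs(a, np.exp(ls), np.exp(lr), cap)
        return -float(np.sum(counts * np.log(np.clip(probs, 1e-300, None))))

    m = max(float(np.average(scores, weights=weights)), 0.05)
    res = optimize.minimize(
        nll,
        [np.log(m) - 0.5, 0.0, np.log(20.0)],
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 3000},
    )
    a, ls, lr = res.x
    return float(a), float(np.exp(ls)), float(np.exp(lr))


def ceiling_attenuation_factor(
    a: float, sigma: float, r: float, cap: int, dt: float = 0.02
) -> float:
    """Local slope of log E[min(S, cap)] per unit shift of the latent log-mean."""

    def log_e_min(t):
        mu = np.exp(np.clip(a + t + sigma * _NODES, -30.0, 30.0))
        P = _nb_pmf_matrix(mu, r, cap)
        e_min = P @ np.arange(cap) + cap * np.clip(1.0 - P.sum(axis=1), 0.0, None)
        return np.log(max(_WTS @ e_min, 1e-300))

    return float((log_e_min(dt) - log_e_min(-dt)) / (2.0 * dt))


def estimate_ceiling_correction(
    scores: np.ndarray, cap: int, weights: np.ndarray | None = None
) -> float:
    """Attenuation factor c in (0, 1] for a bounded score sample.

    Returns 1.0 when the sample carries no mass near the ceiling (no
    correction needed or identifiable).
    """
    scores = np.asarray(scores)
    if scores.size == 0 or scores.max() < 0.75 * cap:
        return 1.0
    a, sigma, r = fit_score_measurement_model(scores, cap, weights=weights)
    c = ceiling_attenuation_factor(a, sigma, r, cap)
    if not np.isfinite(c) or not 0.2 < c <= 1.0 + 1e-9:
        return 1.0
    return min(c, 1.0)
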