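"""Bivariate standard-normal CDF and density.

The CDF uses Owen's T function, which scipy evaluates to near machine
precision; this is the accuracy-critical primitive behind the bivariate
probit likelihood (orthant probabilities).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

_TINY = 1e-14
_BIG_SLOPE = 1e9


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorised over all three arguments.  Accuracy ~1e-14 away from
    |rho| = 1; the |rho| -> 1 limits are handled continuously.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    hs = np.where(np.abs(h) < _TINY, _TINY, h)
    ks = np.where(np.abs(k) < _TINY, _TINY, k)
    sr = np.sqrt(np.clip(1.0 - rho**2, 1e-300, None))
    a1 = np.clip((ks - rho * hs) / (hs * sr), -_BIG_SLOPE, _BIG_SLOPE)
    a2 = np.clip((hs - rho * ks) / (ks * sr), -_BIG_SLOPE, _BIG_SLOPE)
    beta = np.where(hs * ks > 0, 0.0, 0.5)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(hs, a1) - owens_t(ks, a2) - beta
    return np.clip(out, 0.0, 1.0)


def bvn_pdf(h, k, rho):
    """Density of the standard bivariate normal at (h, k)."""
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    rho = np.asarray(rho, float)
    om = 1.0 - rho**2
    z = (h**2 - 2.0 * rho * h * k + k**2) / om
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(om))
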