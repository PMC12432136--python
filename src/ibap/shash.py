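"""Sinh-arcsinh (location-scale-skew) distribution primitives.

The three-parameter family used by the normative charts: if ``Z`` is standard
normal, then ``X = mu + sigma * sinh(asinh(Z) + nu)`` has location ``mu``,
scale ``sigma`` and skewness ``nu`` (``nu = 0`` recovers the Gaussian).  The
CDF and quantile function are analytic, strictly monotone and exact inverses
of each other, which is all the downstream pipeline consumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["shash_cdf", "shash_ppf", "shash_logpdf", "shash_nll", "shash_rvs"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def shash_cdf(x, mu, sigma, nu):
    """CDF of the sinh-arcsinh family; vectorized over all arguments."""
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return ndtr(np.sinh(np.arcsinh(z) - nu))


def shash_ppf(p, mu, sigma, nu):
    """Quantile function; exact inverse of :func:`shash_cdf`."""
    p = np.asarray(p, dtype=float)
    return mu + sigma * np.sinh(np.arcsinh(ndtri(p)) + nu)


def shash_logpdf(x, mu, sigma, nu):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    u = np.arcsinh(z) - nu
    r = np.sinh(u)
    return (
        -0.5 * r * r
        - 0.5 * _LOG_2PI
        + np.log(np.cosh(u))
        - np.log(sigma)
        - 0.5 * np.log1p(z * z)
    )


def shash_nll(x, mu, sigma, nu):
    """Total negative log-likelihood (scalar)."""
    return -float(np.sum(shash_logpdf(x, mu, sigma, nu)))


def shash_rvs(rng: np.random.Generator, mu, sigma, nu, size=None):
    """Draw variates via the quantile transform (keeps draws seedable)."""
    p = rng.uniform(size=size)
    # avoid the open-interval endpoints exactly
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return shash_ppf(p, mu, sigma, nu)
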